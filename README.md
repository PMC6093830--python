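# taupvc

Quantification of hippocampal binding in **dynamic tau-PET** is confounded by
the **choroid plexus (CP)**: a small ventricular structure abutting the
hippocampus with high off-target tracer binding. At clinical PET resolution
(~6 mm FWHM) CP activity spills into the hippocampal volume of interest, so
hippocampal and CP outcome measures correlate even when the underlying
biology is independent. `taupvc` implements the full correction and
quantification chain for this problem:

* **HDH partial-volume correction** — HYPR denoising, Van Cittert iterative
  deconvolution, HYPR again (`f_{k+1} = f_k + α(g − h⊗f_k)` per frame, with
  HYPR rescaling each frame by `composite·smooth(frame)/smooth(composite)`);
* **choroid-plexus-aware VOI erosion** — automatic CP delineation on the
  corrected image and removal of hippocampal voxels within a calibrated
  distance of the CP;
* **2T4k_VB kinetic modelling** — weighted non-linear regression of regional
  TACs with the reversible two-tissue compartment model plus blood volume,
  reporting the distribution volume `V_T = (K1/k2)(1 + k3/k4)`;
* **endpoint statistics** — per-condition OLS of hippocampal on CP V_T
  (slope, r²), a stacked-model interaction (slope-difference) test, and the
  exact paired Wilcoxon signed-rank test;
* a **seeded digital-phantom generator** (dynamic 130-min acquisition with a
  20-min break, Feng-model arterial input with Hill metabolite correction,
  PSF blur, activity-scaled noise) whose ground-truth regional kinetics are
  drawn independently per region — so any observed hippocampus–CP coupling
  is attributable to spill-in, and its removal is verifiable.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Run the full synthetic study replica (20 subjects, four analysis conditions:
complete/eroded hippocampal VOI × with/without PVC):

```bash
tauPVC study --out results/study --seed 1
```

which prints, per scope (pooled and per group), the condition grid and the
headline tests — output from this exact command:

```
[pooled]
  complete_nopvc   slope=+0.541  r2=0.815  n=20
  eroded_nopvc     slope=+0.220  r2=0.385  n=20
  complete_pvc     slope=+0.321  r2=0.520  n=20
  eroded_pvc       slope=+0.072  r2=0.064  n=20
  interaction slope diff=-0.469 p=0.0000; Wilcoxon W+=210.0 p=0.0000
```

Reading it: on uncorrected data with the anatomical (complete) VOI, fitted
hippocampal V_T regresses on CP V_T with slope 0.54 and r² 0.82 — a strong
apparent coupling that is pure spill-in, because the phantom's true V_T
values are independent draws. Erosion alone and PVC alone each reduce it;
PVC combined with the eroded VOI removes it almost entirely (slope 0.07,
r² 0.07). The interaction test confirms the slope difference (p < 0.05), and
the paired Wilcoxon confirms that corrected hippocampal V_T is
systematically lower than uncorrected (spill-in removed; W+ = 210 means all
20 paired differences are positive). `results/study/` holds the V_T table,
per-condition regression summary, scatter/paired TSVs and a provenance JSON.

The pieces are available individually — e.g. correct one scan:

```bash
tauPVC simulate --out data --seed 7 --n-subjects 1
tauPVC pvc --in data/sub-01_pet.nii.gz --frames data/sub-01_frames.tsv \
           --psf-fwhm 6 --iterations 10 --alpha 1.0 --hypr-fwhm 6 \
           --out data/sub-01_hdh.nii.gz
```

or from Python:

```python
from taupvc import (PhantomSpec, CohortSpec, generate_cohort, hdh_pvc,
                    PSFModel, extract_tac, fit_2t4k)

subjects = generate_cohort(CohortSpec(n_subjects=10, seed=1), PhantomSpec())
sub = subjects[0]
corrected, provenance = hdh_pvc(sub.image, PSFModel(fwhm_mm=6.0))
tac = extract_tac(corrected, sub.truth.labels == 1, "hippocampus")
fit = fit_2t4k(tac.values, corrected.frames, sub.plasma)
print(fit.VT, sub.truth.region_vt["hippocampus"])
```

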