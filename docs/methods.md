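# Methods

`taupvc` quantifies hippocampal binding in dynamic tau-PET in the presence of
spill-in from the adjacent choroid plexus (CP), a small ventricular structure
with high off-target tracer binding. The package implements the full
quantification chain — partial-volume correction, VOI definition and erosion,
compartmental fitting to the distribution volume V_T, and the endpoint
statistics — together with a digital-phantom generator that provides ground
truth for validation. This note documents the models, defaults and numerical
choices, and what the synthetic experiments do and do not show.

## Kinetic model (2T4k_VB)

Tissue kinetics follow the reversible two-tissue compartment model with a
fractional blood volume term:

    dC1/dt = K1·Cp − (k2 + k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2
    C_model(t) = (1 − V_B)·(C1 + C2) + V_B·C_wb(t)

with Cp the metabolite-corrected parent plasma curve and C_wb whole blood.
Units: K1 in mL·cm⁻³·min⁻¹, k2–k4 in min⁻¹, V_B unitless, activities Bq/mL,
times minutes. The outcome measure is the total distribution volume

    V_T = (K1/k2)(1 + k3/k4)        (V_T = K1/k2 when k3 = 0).

**Implementation.** The solution is the analytic bi-exponential impulse
response convolved with Cp. The convolution is evaluated exactly for a
piecewise-linear Cp on a uniform 1-s grid via a causal first-order recursion
(`scipy.signal.lfilter`), so quadrature error is far below fit noise; the
repeated-eigenvalue case (k3 = 0, k2 = k4) reduces exactly to the one-tissue
form. Model output is averaged over each acquisition frame (trapezoidal
cumulative integral) before comparison with a TAC. Agreement with a stiff ODE
integration (LSODA, rtol 1e−10) is ~2·10⁻⁴ relative at frame mid-times.

**Fitting.** Weighted non-linear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with weights
proportional to frame duration; eight start points spanning physiological
ranges (K1 ∈ {0.05, 0.3}, k2 ∈ {0.05, 0.2}, k3 = k4 ∈ {0.01, 0.1},
V_B start 0.05); bounds K1 ∈ (1e−4, 2], k2,k3,k4 ∈ (1e−4, 1], V_B ∈ [0, 0.3].
The best converged start wins; asymptotic standard errors come from the
Gauss–Newton covariance. An identically-zero TAC is non-identifiable and is
returned at the lower bounds with a `degenerate` flag. No decay-correction
modelling: activities are assumed decay-corrected upstream.

V_T is markedly more stable than the micro-parameters: at 5% frame noise the
coefficient of variation of V_T is well below that of k3 (asserted on a
100-replicate seeded table).

## Arterial input function

There is no deposited input-function data, so the generator uses standard
closed forms: a Feng tri-exponential plasma model with delay t0
(defaults A1 = 851.1 Bq·mL⁻¹·min⁻¹, A2 = 21.9, A3 = 20.8 Bq/mL;
λ1 = 4.13 > λ2 = 0.12 > λ3 = 0.0104 min⁻¹; t0 = 0.7 min), a Hill parent
fraction pf(t) = 1 − a·t^b/(t^b + c) with pf(0) = 1 and asymptote
1 − a = 0.15 (a = 0.85, b = 1.8, c = 250), giving ~24% parent at 80 min —
in the range typical of flortaucipir — and a saturating plasma-to-whole-blood
ratio R(t) = 1.5 − 0.5·e^(−0.05 t).

## Digital phantom and cohorts

One phantom is a 64³ grid of 2-mm isotropic voxels holding three regions:

* **hippocampus** — ellipsoid with semi-axes 14 × 8 × 6.4 mm (~2.9 cm³);
* **choroid plexus** — the ≤2-mm-thick shell of voxels hugging the
  hippocampal surface inside a spherical cap (direction cosine ≥ 0.30 around
  +y), ~0.6 cm³, face-adjacent to the hippocampus — a thin curved hot
  structure draped over one side, which is what makes its spill-in potent;
* **background** — everything else, with gray-matter-like kinetics
  (V_T ≈ 3). A tissue-like surround was chosen deliberately: with a
  near-empty surround, hippocampal spill-*out* dominates CP spill-*in* and
  the uncorrected hippocampal V_T is biased *low*, which is not the regime
  this analysis chain addresses. With V_T ≈ 3 around a V_T ≈ 4.2
  hippocampus, the net uncorrected bias is positive and CP-driven.

Voxel time courses are the frame-averaged model curves of their region,
blurred per frame by an isotropic Gaussian PSF (default FWHM 6 mm, a typical
clinical PET resolution) and perturbed by seeded Gaussian noise with
standard deviation `noise_scale·sqrt(activity/frame duration)`
(default noise_scale 2, ≈ 10–20% per voxel in late frames — a standard
surrogate for reconstructed-PET noise; Poisson/sinogram realism is out of
scope). The default frame schedule has 23 frames covering 0–60 and
80–130 min with a 20-min break (4×15 s, 4×30 s, 3×60 s, 2×120 s, 10×600 s).

Cohorts (default 20 subjects: 10 "control" + 10 "ad", same distributions)
draw each region's K1, k2, k3, k4, V_B from truncated normals,
**independently per region**, so true hippocampal and CP V_T are
uncorrelated by construction and any fitted correlation is attributable to
spill-in. Defaults give hippocampal V_T 4.2 ± ~0.4 and CP V_T 3.5× hotter
(hot off-target binding) with ~30% spread; the CP K1 mean is solved from the
target `cp_to_hippo_vt_ratio`. Everything is a pure function of the seeds.

## HDH partial-volume correction

The chain is HYPR → Van Cittert → HYPR, per frame in image space, with
reflective boundary handling:

* **HYPR denoising**: `out_f = composite · smooth(frame_f)/smooth(composite)`
  with the composite the frame-duration-weighted mean of the current series
  and a 6-mm FWHM Gaussian smoothing kernel. Voxels where the smoothed
  composite is below 1e−9 of its maximum pass through unchanged (0/0 guard).
  The second pass recomputes the composite from the deconvolved series.
* **Van Cittert deconvolution**: f₀ = g, f_{k+1} = clip(f_k + α(g − h⊗f_k)),
  default α = 1.0 and 10 iterations; negatives are clipped after each step
  because activity is non-negative and unconstrained VC rings. The residual
  norm ‖g − h⊗f_k‖₂ is recorded per iteration in the provenance sidecar, and
  a >10% between-iteration increase is flagged as an instability warning.

Known properties, verified in tests: with a delta PSF the VC step is exactly
the identity; with frames proportional to the composite the full chain is the
identity; the chain is not idempotent; HYPR preserves means in uniform
neighbourhoods but *mixes temporal shapes across region borders*, so a thin
structure's label mean can shift several percent even with nothing to
correct — a real HYPR trade-off, not an implementation artefact. Ten VC
iterations under-restore a 2-mm-thin CP (its recovered mean stays below
truth); what matters for the endpoint is that the hippocampal CP-driven
component is removed.

## VOIs, CP delineation and erosion

TACs are arithmetic in-mask means per frame. The complete hippocampal VOI is
the phantom's anatomical label (standing in for an atlas VOI). The CP mask is
delineated automatically on the corrected image — a reproducible surrogate
for manual drawing: the late-frame average (last 25 min, duration-weighted),
lightly smoothed (3 mm FWHM) to suppress isolated deconvolution spikes, is
thresholded inside an anatomical search shell (the hippocampal VOI dilated by
10 mm, minus the VOI). The threshold is the larger of 2× the background
label's late mean and half the late 99th percentile inside the shell — the
adaptive part keeps the mask compact when the blurred hippocampal rim enters
the shell, and a percentile (rather than the maximum) resists isolated
deconvolution overshoots — capped at 80% of the shell maximum so the hottest
structure is never thresholded away when a subject's background runs high.
The largest connected component is kept. On the default phantom this
recovers the true CP with Dice ≈ 0.7; across noisy cohort draws Dice varies
(≈ 0.3–0.85) with the subject's CP-to-surround contrast, which the endpoint
statistics tolerate.

The eroded hippocampal VOI removes every voxel whose Euclidean
centre-to-centre distance (via a distance transform of the CP mask) is
≤ `erode_radius_mm`. The default radius of 4.0 mm was calibrated once so the
default phantom loses ~40% of its hippocampal voxels, matching the fraction
the clinical procedure reports; removal is monotone in the radius. Masks are
never resampled; phantom and analysis share one grid.

## Endpoint statistics

For each condition (complete/eroded VOI × with/without PVC) hippocampal V_T
is regressed on CP V_T (OLS; r² is the squared Pearson correlation; a
constant response returns slope 0, r² 0). The slope difference between two
conditions is tested with a single stacked model
`hippo_VT ~ CP_VT × condition` (Wald test on the interaction coefficient).
Paired V_T comparisons use the Wilcoxon signed-rank test with Pratt handling
of zero differences, mid-ranks for ties, and the exact sign-flip distribution
(dynamic-programming convolution; ranks doubled so mid-ranks stay integral)
for up to 25 non-zero pairs — exactness matters at n = 10–20 — with a
tie-corrected normal approximation above. The pipeline treats paired V_T
differences below 1e−9 (relative) as null, so analytically identical branches
compare as ties. Statistics are reported pooled and per group; groups too
small for a statistic omit it.

## The study replica

`run_study` renders each subject, applies HDH on one branch, delineates the
CP on the corrected image (used for both branches, as the CP is drawn once),
builds complete and eroded VOIs, fits all six TACs (4 hippocampal conditions
+ CP on both branches) and tabulates V_T; then computes the statistics. With
default settings the uncorrected complete-VOI regression shows a clear
spill-in-induced coupling (slope > 0.3, r² > 0.3 pooled), PVC + erosion cuts
the slope by more than half, the interaction test and the paired Wilcoxon
(corrected values lower) reject at 5% — the qualitative pattern of the
clinical analysis, reproduced on cohorts where the true V_T are independent
by construction. Everything is deterministic under the master seed, and the
uncorrected branch is exactly `extract_tac` + `fit_2t4k` on the raw phantom.

Problem sizes used by the test suite and `scripts/acceptance.py` (64³ grids,
23 frames, 20 subjects, five master seeds for the endpoint property, 100
noisy replicates for the recovery table) were chosen as the smallest sizes
at which the phantom still exhibits the study's spill-in regime clearly.

## Limitations

* The phantom is three-region, piecewise-constant, with Gaussian noise and a
  shift-invariant Gaussian PSF; no anatomy, atrophy, motion, registration
  error or reconstruction artefacts. Passing tests show the chain removes
  *PSF-induced* coupling under these conditions, not that clinical values
  are reproduced.
* HYPR's temporal-shape mixing near borders biases thin-structure TAC shapes;
  the chain's benefit is assessed on the endpoint, not voxelwise accuracy.
* Ten VC iterations trade restoration against noise amplification; the count
  and α are exposed in `HDHConfig` rather than asserted as validated values.
* Absolute hippocampal V_T after PVC + erosion remains biased for thin VOIs
  (every hippocampal voxel is within ~one PSF width of a boundary); the
  endpoint is the removal of the CP association and the paired decrease.
* The automatic CP delineation substitutes for manual drawing; its threshold
  rule was designed for this phantom's contrast and may need retuning for
  other geometries.
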