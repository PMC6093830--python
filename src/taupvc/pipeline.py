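"""End-to-end study replica: cohort -> PVC -> VOIs -> kinetics -> statistics.

For every synthetic subject the study renders a dynamic phantom, processes
it along two branches (uncorrected, and HDH partial-volume corrected),
delineates the choroid plexus on the corrected image, builds complete and
eroded hippocampal VOIs, extracts TACs for the four analysis conditions
(complete/eroded VOI x with/without PVC), fits the 2T4k_VB model to each
TAC and tabulates V_T.  The endpoint statistics then quantify how much of
the apparent hippocampus-CP coupling each condition removes.

Everything is deterministic under the master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import InsufficientDataError, TauPVCError
from .kinetics import FitSettings, fit_2t4k
from .phantom import CohortSpec, PhantomSpec, RegionGeometry, Subject, generate_cohort
from .pvc import HDHConfig, PSFModel, hdh_pvc
from .stats import interaction_test, regress_vt, wilcoxon_signed_rank
from .voi import DEFAULT_ERODE_RADIUS_MM, delineate_cp, erode_hippocampus, extract_tac
from scipy import ndimage

__all__ = ["StudyConfig", "StudyReport", "run_study", "write_report", "CONDITIONS"]

#: the four analysis conditions, uncorrected first
CONDITIONS = ("complete_nopvc", "eroded_nopvc", "complete_pvc", "eroded_pvc")

#: the headline contrast: anatomical VOI without PVC vs eroded VOI with PVC
PRIMARY_CONTRAST = ("complete_nopvc", "eroded_pvc")


@dataclass
class StudyConfig:
    """All knobs of one study run (flat, YAML-serialisable)."""

    n_subjects: int = 20
    master_seed: int = 0
    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    psf_fwhm_mm: float = 6.0
    noise_scale: float = 2.0
    cp_to_hippo_vt_ratio: float = 3.5
    independent_regions: bool = True
    vc_iterations: int = 10
    vc_step: float = 1.0
    hypr_filter_fwhm_mm: float = 6.0
    erode_radius_mm: float = DEFAULT_ERODE_RADIUS_MM
    cp_threshold_factor: float = 2.0
    cp_search_dilation_mm: float = 10.0

    def phantom_spec(self, seed: int = 0) -> PhantomSpec:
        return PhantomSpec(
            grid_shape=tuple(self.grid_shape),
            voxel_size_mm=tuple(self.voxel_size_mm),
            geometry=RegionGeometry(),
            psf_fwhm_mm=self.psf_fwhm_mm,
            noise_scale=self.noise_scale,
            seed=seed,
        )

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_subjects=self.n_subjects,
            cp_to_hippo_vt_ratio=self.cp_to_hippo_vt_ratio,
            independent_regions=self.independent_regions,
            seed=self.master_seed,
        )

    def hdh_config(self) -> HDHConfig:
        return HDHConfig(
            vc_iterations=self.vc_iterations,
            vc_step=self.vc_step,
            hypr_filter_fwhm_mm=self.hypr_filter_fwhm_mm,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "voxel_size_mm" in d:
            d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Everything the study computed, ready for serialisation."""

    vt_table: pd.DataFrame
    regressions: dict  # scope -> condition -> RegressionResult
    interactions: dict  # scope -> InteractionResult
    wilcoxon: dict  # scope -> WilcoxonResult
    erosion: dict  # subject -> erosion record
    failures: list
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "vt_table": self.vt_table.to_dict(orient="records"),
            "regressions": {
                scope: {cond: asdict(r) for cond, r in conds.items()}
                for scope, conds in self.regressions.items()
            },
            "interactions": {s: asdict(r) for s, r in self.interactions.items()},
            "wilcoxon": {s: asdict(r) for s, r in self.wilcoxon.items()},
            "erosion": self.erosion,
            "failures": self.failures,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=True)


def _analyse_subject(
    subject: Subject, config: StudyConfig, fit_settings: FitSettings
) -> tuple[list, dict]:
    """VT rows for the four conditions of one subject, plus erosion record."""
    img = subject.image
    truth = subject.truth
    psf = PSFModel(fwhm_mm=config.psf_fwhm_mm)
    img_pvc, _prov = hdh_pvc(img, psf, config.hdh_config())

    hippo_complete = truth.labels == 1
    background = truth.labels == 0

    # anatomical prior for the CP search: a shell around the hippocampus VOI
    sigma_mask = np.asarray(config.voxel_size_mm, float)
    n_dilate = np.maximum(
        1, np.round(config.cp_search_dilation_mm / sigma_mask).astype(int)
    )
    struct = ndimage.generate_binary_structure(3, 1)
    search = (
        ndimage.binary_dilation(hippo_complete, struct, iterations=int(n_dilate.max()))
        & ~hippo_complete
    )
    cp_mask, cp_record = delineate_cp(
        img_pvc,
        background_mask=background,
        search_mask=search,
        threshold_factor=config.cp_threshold_factor,
    )
    hippo_eroded, erosion_record = erode_hippocampus(
        hippo_complete, cp_mask, config.erode_radius_mm, img.voxel_size
    )
    erosion_record["cp_delineation"] = cp_record

    branches = {"nopvc": img, "pvc": img_pvc}
    masks = {"complete": hippo_complete, "eroded": hippo_eroded}
    cp_vt = {}
    for branch, bimg in branches.items():
        tac = extract_tac(bimg, cp_mask, region="choroid_plexus")
        fit = fit_2t4k(tac.values, bimg.frames, subject.plasma, settings=fit_settings)
        cp_vt[branch] = fit.VT

    rows = []
    for voi_name, mask in masks.items():
        for branch, bimg in branches.items():
            tac = extract_tac(bimg, mask, region=f"hippocampus_{voi_name}")
            fit = fit_2t4k(tac.values, bimg.frames, subject.plasma, settings=fit_settings)
            rows.append(
                {
                    "subject": subject.subject_id,
                    "group": subject.group,
                    "condition": f"{voi_name}_{branch}",
                    "hippo_vt": fit.VT,
                    "cp_vt": cp_vt[branch],
                    "true_hippo_vt": truth.region_vt["hippocampus"],
                    "true_cp_vt": truth.region_vt["choroid_plexus"],
                    "n_voxels": tac.n_voxels,
                }
            )
    return rows, erosion_record


def _scope_stats(df: pd.DataFrame):
    """Per-scope statistics; entries the sample size cannot support are None."""
    regs = inter = wil = None
    n = df["subject"].nunique()
    if n >= 3:
        regs = {}
        for cond in CONDITIONS:
            sub = df[df["condition"] == cond]
            regs[cond] = regress_vt(sub["cp_vt"].to_numpy(), sub["hippo_vt"].to_numpy())
    if n >= 4:
        inter = interaction_test(df, *PRIMARY_CONTRAST)
    a = df[df["condition"] == PRIMARY_CONTRAST[0]].sort_values("subject")
    b = df[df["condition"] == PRIMARY_CONTRAST[1]].sort_values("subject")
    try:
        # V_T differences at float resolution are null, not signal
        wil = wilcoxon_signed_rank(
            a["hippo_vt"].to_numpy(), b["hippo_vt"].to_numpy(), zero_tol=1e-9
        )
    except InsufficientDataError:
        wil = None
    return regs, inter, wil


def run_study(config: StudyConfig, fit_settings: FitSettings | None = None) -> StudyReport:
    """Execute the full study replica. Deterministic under the master seed."""
    fit_settings = fit_settings or FitSettings()
    spec = config.phantom_spec()
    cohort = config.cohort_spec()
    subjects = generate_cohort(cohort, spec)

    rows: list = []
    erosion: dict = {}
    failures: list = []
    for subject in subjects:
        try:
            sub_rows, erec = _analyse_subject(subject, config, fit_settings)
        except TauPVCError as exc:
            failures.append(
                {"subject": subject.subject_id, "stage": "analysis", "error": str(exc)}
            )
            continue
        rows.extend(sub_rows)
        erosion[subject.subject_id] = erec
    if len(failures) > 0.2 * len(subjects):
        raise TauPVCError(
            f"study failed: {len(failures)}/{len(subjects)} subjects aborted"
        )

    vt_table = pd.DataFrame(rows)
    regressions: dict = {}
    interactions: dict = {}
    wilcoxon: dict = {}
    scopes = {"pooled": vt_table}
    for group, gdf in vt_table.groupby("group"):
        scopes[group] = gdf
    for scope, df in scopes.items():
        regs, inter, wil = _scope_stats(df)
        if regs is not None:
            regressions[scope] = regs
        if inter is not None:
            interactions[scope] = inter
        if wil is not None:
            wilcoxon[scope] = wil

    provenance = {
        "taupvc_version": __version__,
        "master_seed": config.master_seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_subjects": len(subjects),
        "n_failed": len(failures),
        "conditions": list(CONDITIONS),
        "primary_contrast": list(PRIMARY_CONTRAST),
    }
    return StudyReport(
        vt_table=vt_table,
        regressions=regressions,
        interactions=interactions,
        wilcoxon=wilcoxon,
        erosion=erosion,
        failures=failures,
        provenance=provenance,
    )


def write_report(report: StudyReport, outdir) -> dict:
    """Emit the report as TSV/JSON files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vt_table": outdir / "vt_table.tsv",
        "regressions": outdir / "regression_summary.tsv",
        "scatter": outdir / "scatter_data.tsv",
        "paired": outdir / "paired_vt.tsv",
        "report": outdir / "report.json",
        "provenance": outdir / "provenance.json",
    }
    report.vt_table.to_csv(paths["vt_table"], sep="\t", index=False)

    reg_rows = []
    for scope, conds in report.regressions.items():
        for cond, r in conds.items():
            reg_rows.append({"scope": scope, "condition": cond, **asdict(r)})
    pd.DataFrame(reg_rows).to_csv(paths["regressions"], sep="\t", index=False)

    scatter = report.vt_table[
        report.vt_table["condition"].isin(PRIMARY_CONTRAST)
    ][["subject", "group", "condition", "cp_vt", "hippo_vt"]]
    scatter.to_csv(paths["scatter"], sep="\t", index=False)

    wide = report.vt_table.pivot_table(
        index=["subject", "group"], columns="condition", values="hippo_vt"
    ).reset_index()
    wide.columns.name = None
    wide.to_csv(paths["paired"], sep="\t", index=False)

    Path(paths["report"]).write_text(report.to_json())
    Path(paths["provenance"]).write_text(
        json.dumps(report.provenance, indent=2, sort_keys=True)
    )
    return {k: str(v) for k, v in paths.items()}
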