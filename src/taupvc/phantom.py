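"""Seeded digital phantoms for dynamic tau-PET with choroid-plexus spill-in.

The phantom emulates a 130-min dynamic acquisition with a 20-min break
after the first 60 min: an ellipsoidal hippocampus (~3 cm^3) with a thin
curved choroid-plexus (CP) shell (~0.5 cm^3) hugging one face of its
surface, embedded in a uniform soft-tissue background.  Every region gets
its own 2T4k_VB kinetics; voxel time courses are the frame-averaged model
curves, blurred by an isotropic Gaussian scanner PSF (creating the CP ->
hippocampus spill-in the correction chain is meant to remove) and
perturbed by seeded Gaussian noise with variance proportional to
activity / frame duration.

Cohorts draw each subject's regional kinetic parameters independently per
region, so any correlation between fitted hippocampal and CP V_T in a
blurred cohort is attributable to spill-in, not shared biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError, ConfigurationError, ParameterError
from .image import DynamicImage, FrameSchedule
from .kinetics import KineticParams, PlasmaInput, compute_vt, model_frame_means

__all__ = [
    "InputFunctionParams",
    "RegionGeometry",
    "PhantomSpec",
    "TruncNormal",
    "CohortSpec",
    "Subject",
    "PhantomTruth",
    "feng_input",
    "parent_fraction",
    "apply_metabolite_correction",
    "make_plasma_input",
    "build_geometry",
    "simulate_region_tac",
    "render_dynamic_phantom",
    "draw_subject_params",
    "generate_cohort",
    "default_frame_schedule",
]

#: integer region labels
LABELS = {"background": 0, "hippocampus": 1, "choroid_plexus": 2}


def default_frame_schedule() -> FrameSchedule:
    """23 frames spanning 0-60 and 80-130 min with a 20-min break.

    4x15 s, 4x30 s, 3x60 s, 2x120 s and 5x600 s cover the first hour;
    5x600 s cover 80-130 min after the break.
    """
    durations = [15] * 4 + [30] * 4 + [60] * 3 + [120] * 2 + [600] * 5
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    starts2 = 4800.0 + 600.0 * np.arange(5)
    return FrameSchedule(
        np.concatenate([starts, starts2]),
        np.array(durations + [600.0] * 5),
    )


# ---------------------------------------------------------------------------
# Arterial input function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputFunctionParams:
    """Feng tri-exponential plasma model with delay, Hill parent fraction
    and a saturating plasma-to-whole-blood ratio.

    Total plasma activity for t > t0 (t in minutes):

        Cp(t') = (A1*t' - A2 - A3) e^(-l1 t') + A2 e^(-l2 t') + A3 e^(-l3 t')

    with t' = t - t0; zero before the delay.  Parent fraction follows a
    Hill curve pf(t) = 1 - a t^b / (t^b + c) (pf(0) = 1, asymptote 1 - a).
    Plasma/whole-blood ratio R(t) = r_inf - (r_inf - r0) e^(-k_r t).
    """

    A1: float = 851.1  # Bq·mL^-1·min^-1
    A2: float = 21.9  # Bq/mL
    A3: float = 20.8  # Bq/mL
    l1: float = 4.13  # min^-1
    l2: float = 0.12  # min^-1
    l3: float = 0.0104  # min^-1
    t0: float = 0.7  # min
    hill_a: float = 0.85
    hill_b: float = 1.8
    hill_c: float = 250.0  # min^hill_b
    pwb_r0: float = 1.0
    pwb_rinf: float = 1.5
    pwb_k: float = 0.05  # min^-1

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 > self.l3 > 0):
            raise ParameterError("eigenvalues must satisfy l1 > l2 > l3 > 0")
        if not (0 <= self.hill_a < 1):
            raise ParameterError("parent fraction must stay in (0, 1]: need 0 <= hill_a < 1")
        if self.hill_b <= 0 or self.hill_c <= 0:
            raise ParameterError("Hill shape parameters must be positive")

    @property
    def parent_fraction_asymptote(self) -> float:
        return 1.0 - self.hill_a


def feng_input(params: InputFunctionParams, times: np.ndarray) -> np.ndarray:
    """Total plasma activity on a non-negative, increasing time grid (min)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ParameterError("times must be non-negative and increasing")
    tp = times - params.t0
    curve = np.where(
        tp > 0,
        (params.A1 * tp - params.A2 - params.A3) * np.exp(-params.l1 * np.maximum(tp, 0))
        + params.A2 * np.exp(-params.l2 * np.maximum(tp, 0))
        + params.A3 * np.exp(-params.l3 * np.maximum(tp, 0)),
        0.0,
    )
    return np.clip(curve, 0.0, None)


def parent_fraction(params: InputFunctionParams, times: np.ndarray) -> np.ndarray:
    """Hill-model fraction of total plasma activity that is parent tracer."""
    t = np.asarray(times, dtype=float)
    tb = np.power(np.maximum(t, 0.0), params.hill_b)
    return 1.0 - params.hill_a * tb / (tb + params.hill_c)


def apply_metabolite_correction(
    curve: np.ndarray, params: InputFunctionParams, times: np.ndarray
) -> np.ndarray:
    """Parent plasma curve = total plasma x Hill parent fraction."""
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if curve.shape != times.shape:
        raise ParameterError("curve and times must have the same length")
    frac = parent_fraction(params, times)
    if np.any(frac <= 0) or np.any(frac > 1 + 1e-12):
        raise ParameterError("parent fraction left (0, 1]")
    return curve * frac


def make_plasma_input(
    params: InputFunctionParams | None = None,
    t_end_min: float = 130.0,
    dt_min: float = 1.0 / 60.0,
) -> PlasmaInput:
    """Build a synthetic metabolite-corrected :class:`PlasmaInput`."""
    params = params or InputFunctionParams()
    times = np.arange(0.0, t_end_min + dt_min / 2, dt_min)
    total = feng_input(params, times)
    parent = apply_metabolite_correction(total, params, times)
    ratio = params.pwb_rinf - (params.pwb_rinf - params.pwb_r0) * np.exp(-params.pwb_k * times)
    whole_blood = total / ratio
    return PlasmaInput(times=times, parent_plasma=parent, whole_blood=whole_blood)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionGeometry:
    """Parametric hippocampus + choroid-plexus layout (all in mm).

    The hippocampus is an ellipsoid; the CP is the thin shell of voxels
    within ``cp_thickness_mm`` of the hippocampal surface, restricted to a
    spherical cap around ``cp_cap_axis`` (so it curves along the surface,
    sharing faces with the hippocampus).
    """

    hippo_center_mm: tuple = (0.0, 0.0, 0.0)  # offset from volume centre
    hippo_semiaxes_mm: tuple = (14.0, 8.0, 6.4)
    cp_thickness_mm: float = 2.0
    cp_cap_axis: tuple = (0.0, 1.0, 0.0)
    cp_cap_cos: float = 0.30


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic dynamic acquisition."""

    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    geometry: RegionGeometry = field(default_factory=RegionGeometry)
    psf_fwhm_mm: float = 6.0
    noise_scale: float = 2.0
    frames: FrameSchedule = field(default_factory=default_frame_schedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError("grid shape and voxel size must be positive")
        if self.psf_fwhm_mm < 0 or self.noise_scale < 0:
            raise ParameterError("psf_fwhm_mm and noise_scale must be non-negative")
        if any(a <= 0 for a in self.geometry.hippo_semiaxes_mm):
            raise GeometryError("hippocampus semi-axes must be positive")
        if self.geometry.cp_thickness_mm <= 0:
            raise GeometryError("choroid plexus thickness must be positive")


def _voxel_centres_mm(spec: PhantomSpec):
    """World coordinates (mm) of voxel centres along each axis."""
    axes = []
    for n, v in zip(spec.grid_shape, spec.voxel_size_mm):
        axes.append((np.arange(n) - (n - 1) / 2.0) * v)
    return np.meshgrid(*axes, indexing="ij")


def build_geometry(spec: PhantomSpec) -> np.ndarray:
    """3D integer label volume: 0 background, 1 hippocampus, 2 choroid plexus."""
    geom = spec.geometry
    xx, yy, zz = _voxel_centres_mm(spec)
    cx, cy, cz = geom.hippo_center_mm
    a, b, c = geom.hippo_semiaxes_mm
    dx, dy, dz = xx - cx, yy - cy, zz - cz
    ell = (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2
    hippo = ell <= 1.0
    if not hippo.any():
        raise GeometryError("hippocampus region is empty on this grid")
    # bounds check: region must not touch the volume edge
    for axis in range(3):
        edge = [slice(None)] * 3
        for idx in (0, -1):
            edge[axis] = idx
            if hippo[tuple(edge)].any():
                raise GeometryError("hippocampus extends outside the grid interior")

    # CP: shell within cp_thickness of the hippocampal surface, cap-restricted
    dist_mm = ndimage.distance_transform_edt(~hippo, sampling=spec.voxel_size_mm)
    axis = np.asarray(geom.cp_cap_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("cp_cap_axis must be a non-zero direction")
    axis = axis / norm
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (dx * axis[0] + dy * axis[1] + dz * axis[2]) / np.where(r > 0, r, np.inf)
    cp = (~hippo) & (dist_mm > 0) & (dist_mm <= geom.cp_thickness_mm) & (cosang >= geom.cp_cap_cos)
    if not cp.any():
        raise GeometryError("choroid plexus region is empty (zero extent)")
    for ax3 in range(3):
        edge = [slice(None)] * 3
        for idx in (0, -1):
            edge[ax3] = idx
            if cp[tuple(edge)].any():
                raise GeometryError("choroid plexus extends outside the grid interior")

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[hippo] = LABELS["hippocampus"]
    labels[cp] = LABELS["choroid_plexus"]

    if cp.sum() >= hippo.sum():
        raise GeometryError("choroid plexus must be smaller than the hippocampus")
    if not _face_adjacent(hippo, cp):
        raise GeometryError("choroid plexus is not face-adjacent to the hippocampus")
    return labels


def _face_adjacent(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
    """True if any voxel of a shares a face with a voxel of b."""
    struct = ndimage.generate_binary_structure(3, 1)
    return bool((ndimage.binary_dilation(mask_a, struct) & mask_b).any())


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------


def simulate_region_tac(
    params: KineticParams, plasma: PlasmaInput, frames: FrameSchedule
) -> np.ndarray:
    """Noise-free frame-averaged 2T4k_VB tissue curve for one region."""
    tac = model_frame_means(params, plasma, frames)
    return np.clip(tac, 0.0, None)


@dataclass
class PhantomTruth:
    """Ground truth attached to one rendered phantom."""

    labels: np.ndarray
    region_params: dict
    region_tacs: dict
    region_vt: dict


def render_dynamic_phantom(
    spec: PhantomSpec,
    region_params: dict,
    plasma: PlasmaInput,
) -> tuple[DynamicImage, PhantomTruth]:
    """Render a seeded 4D phantom: region TACs -> PSF blur -> noise.

    ``region_params`` maps region name (background, hippocampus,
    choroid_plexus) to a :class:`KineticParams`.  With ``psf_fwhm_mm = 0``
    and ``noise_scale = 0`` every voxel carries exactly its region's
    noise-free TAC.
    """
    labels = build_geometry(spec)
    missing = [name for name in LABELS if name not in region_params]
    if missing:
        raise ConfigurationError(f"missing kinetic parameters for labels: {missing}")

    tacs = {
        name: simulate_region_tac(region_params[name], plasma, spec.frames)
        for name in LABELS
    }
    n_frames = spec.frames.n_frames
    data = np.zeros((*spec.grid_shape, n_frames), dtype=np.float64)
    for name, lab in LABELS.items():
        mask = labels == lab
        data[mask, :] = tacs[name]

    if spec.psf_fwhm_mm > 0:
        sigma_vox = (spec.psf_fwhm_mm / 2.3548200450309493) / np.asarray(spec.voxel_size_mm)
        for f in range(n_frames):
            data[..., f] = ndimage.gaussian_filter(data[..., f], sigma_vox, mode="reflect")

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        dur_min = spec.frames.duration_min
        sd = spec.noise_scale * np.sqrt(np.clip(data, 0.0, None) / dur_min)
        data = data + rng.standard_normal(data.shape) * sd

    img = DynamicImage(
        voxel_data=data, frames=spec.frames, voxel_size=np.asarray(spec.voxel_size_mm)
    )
    truth = PhantomTruth(
        labels=labels,
        region_params=dict(region_params),
        region_tacs=tacs,
        region_vt={name: compute_vt(p) for name, p in region_params.items()},
    )
    return img, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution truncated to [lo, hi] by redraw."""

    mean: float
    sd: float
    lo: float = 1e-6
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("sd must be non-negative")
        if not (self.lo < self.hi):
            raise ParameterError("need lo < hi")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.lo, self.hi))
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return float(x)
        raise ParameterError("truncated-normal rejection failed; bounds too tight")


def default_param_distributions(cp_to_hippo_vt_ratio: float = 3.5) -> dict:
    """Per-region 2T4k_VB parameter distributions for the default cohort.

    The CP K1 mean is scaled so the mean CP V_T is ``cp_to_hippo_vt_ratio``
    times the mean hippocampal V_T; hippocampal and CP parameters are
    drawn independently.
    """
    hippo = {
        "K1": TruncNormal(0.25, 0.012, 0.02, 1.5),
        "k2": TruncNormal(0.15, 0.008, 0.02, 0.8),
        "k3": TruncNormal(0.03, 0.002, 1e-4, 0.5),
        "k4": TruncNormal(0.02, 0.0015, 1e-3, 0.5),
        "VB": TruncNormal(0.05, 0.01, 0.0, 0.3),
    }
    hippo_vt_mean = (0.25 / 0.15) * (1 + 0.03 / 0.02)
    cp_k2, cp_k3, cp_k4 = 0.12, 0.06, 0.02
    cp_k1_mean = cp_to_hippo_vt_ratio * hippo_vt_mean * cp_k2 / (1 + cp_k3 / cp_k4)
    cp = {
        "K1": TruncNormal(cp_k1_mean, 0.22 * cp_k1_mean, 0.02, 2.0),
        "k2": TruncNormal(cp_k2, 0.008, 0.02, 0.8),
        "k3": TruncNormal(cp_k3, 0.012, 1e-4, 0.5),
        "k4": TruncNormal(cp_k4, 0.004, 1e-3, 0.5),
        "VB": TruncNormal(0.08, 0.015, 0.0, 0.3),
    }
    background = {
        "K1": TruncNormal(0.12, 0.008, 0.02, 1.0),
        "k2": TruncNormal(0.04, 0.003, 0.01, 0.8),
        "k3": TruncNormal(0.0, 0.0, -1e-12, 0.5),
        "k4": TruncNormal(0.0, 0.0, -1e-12, 0.5),
        "VB": TruncNormal(0.03, 0.005, 0.0, 0.3),
    }
    return {"hippocampus": hippo, "choroid_plexus": cp, "background": background}


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort: two groups of subjects with independent regional kinetics."""

    n_subjects: int = 20
    cp_to_hippo_vt_ratio: float = 3.5
    distributions: dict | None = None
    independent_regions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ParameterError("a cohort needs at least 3 subjects")
        if self.cp_to_hippo_vt_ratio <= 1:
            raise ParameterError("cp_to_hippo_vt_ratio must exceed 1 (CP is the hot structure)")

    def resolved_distributions(self) -> dict:
        return self.distributions or default_param_distributions(self.cp_to_hippo_vt_ratio)


@dataclass
class Subject:
    """One synthetic participant."""

    subject_id: str
    group: str  # "control" or "ad"
    image: DynamicImage | None
    plasma: PlasmaInput
    truth: PhantomTruth | None
    true_params: dict


def draw_subject_params(dists: dict, rng: np.random.Generator) -> dict:
    """One independent draw of per-region kinetic parameters."""
    out = {}
    for region, dd in dists.items():
        k3 = dd["k3"].draw(rng)
        k4 = dd["k4"].draw(rng)
        if k3 <= 0:
            k3, k4 = 0.0, 0.0
        out[region] = KineticParams(
            K1=dd["K1"].draw(rng),
            k2=dd["k2"].draw(rng),
            k3=k3,
            k4=k4,
            VB=dd["VB"].draw(rng),
        )
    return out


def generate_cohort(
    cohort: CohortSpec,
    spec: PhantomSpec,
    input_params: InputFunctionParams | None = None,
    render: bool = True,
) -> list[Subject]:
    """Seeded cohort of phantoms with independently drawn regional kinetics.

    The first half of the subjects is labelled ``control`` and the second
    half ``ad`` (the analogue of a patient group); both share the same
    parameter distributions, as hippocampal tracer uptake does not separate
    the groups.  Deterministic: same (CohortSpec, PhantomSpec) -> same cohort.
    """
    dists = cohort.resolved_distributions()
    rng = np.random.default_rng(cohort.seed)
    t_end = float(spec.frames.end_s.max()) / 60.0
    plasma = make_plasma_input(input_params, t_end_min=t_end)
    n_control = (cohort.n_subjects + 1) // 2
    subjects = []
    for i in range(cohort.n_subjects):
        params = draw_subject_params(dists, rng)
        if not cohort.independent_regions:
            # negative-control mode: couple CP uptake to the hippocampal draw
            hippo_vt = compute_vt(params["hippocampus"])
            mean_vt = (0.25 / 0.15) * (1 + 0.03 / 0.02)
            cp = params["choroid_plexus"]
            params["choroid_plexus"] = replace(cp, K1=cp.K1 * hippo_vt / mean_vt)
        subject_seed = int(rng.integers(0, 2**31 - 1))
        image = truth = None
        if render:
            sub_spec = replace(spec, seed=subject_seed)
            image, truth = render_dynamic_phantom(sub_spec, params, plasma)
        subjects.append(
            Subject(
                subject_id=f"sub-{i + 1:02d}",
                group="control" if i < n_control else "ad",
                image=image,
                plasma=plasma,
                truth=truth,
                true_params=params,
            )
        )
    return subjects
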