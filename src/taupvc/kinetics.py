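"""Reversible two-tissue compartment model with blood volume (2T4k_VB).

The tissue model is

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2
    C_model(t) = (1 - VB) * (C1 + C2) + VB * C_wb(t)

with Cp the metabolite-corrected parent plasma curve and C_wb whole blood.
The solution is an analytic bi-exponential impulse response convolved with
Cp; the convolution is evaluated exactly for a piecewise-linear Cp on a
uniform fine grid (a causal first-order recursion per exponential), then
averaged over acquisition frames.  The outcome measure is the total
distribution volume

    V_T = (K1/k2) * (1 + k3/k4).

Units: K1 in mL·cm^-3·min^-1; k2, k3, k4 in min^-1; VB unitless; times in
minutes; activities in Bq/mL.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .exceptions import FitError, IrreversibleModelError, ParameterError
from .image import FrameSchedule

__all__ = [
    "PlasmaInput",
    "KineticParams",
    "FitResult",
    "FitSettings",
    "model_2t4k",
    "compute_vt",
    "fit_2t4k",
    "frame_average",
]

#: fine quadrature step for the convolution, minutes (1 s)
FINE_DT_MIN = 1.0 / 60.0


@dataclass(frozen=True)
class PlasmaInput:
    """Metabolite-corrected plasma input and whole-blood curve.

    ``times`` are minutes post injection, strictly increasing from >= 0;
    both activity curves live on that common time base.
    """

    times: np.ndarray
    parent_plasma: np.ndarray
    whole_blood: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        cp = np.asarray(self.parent_plasma, dtype=float)
        wb = np.asarray(self.whole_blood, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "parent_plasma", cp)
        object.__setattr__(self, "whole_blood", wb)
        if t.ndim != 1 or t.shape != cp.shape or t.shape != wb.shape:
            raise ParameterError("times, parent_plasma, whole_blood must be 1D, equal length")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ParameterError("times must be strictly increasing from >= 0")
        if np.any(cp < 0) or np.any(wb < 0):
            raise ParameterError("plasma activities must be non-negative")

    def sample(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of (parent plasma, whole blood) at ``t``.

        Zero before the first sample; constant extrapolation after the last.
        """
        cp = np.interp(t, self.times, self.parent_plasma, left=0.0)
        wb = np.interp(t, self.times, self.whole_blood, left=0.0)
        return cp, wb


@dataclass(frozen=True)
class KineticParams:
    """Micro-parameters of the 2T4k_VB model for one region."""

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    VB: float = 0.0

    def __post_init__(self) -> None:
        if not (self.K1 > 0 and self.k2 > 0):
            raise ParameterError("K1 and k2 must be positive")
        if self.k3 < 0 or self.k4 < 0:
            raise ParameterError("k3 and k4 must be non-negative")
        if self.k3 > 0 and self.k4 == 0:
            raise ParameterError("reversible model requires k4 > 0 when k3 > 0")
        if not (0 <= self.VB < 1):
            raise ParameterError("VB must be in [0, 1)")

    @property
    def VT(self) -> float:
        return compute_vt(self)

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4, self.VB])


def compute_vt(params: KineticParams) -> float:
    """Total distribution volume V_T = (K1/k2) * (1 + k3/k4)."""
    if params.k3 > 0:
        if params.k4 == 0:
            raise IrreversibleModelError("V_T undefined: k3 > 0 with k4 = 0")
        return (params.K1 / params.k2) * (1.0 + params.k3 / params.k4)
    return params.K1 / params.k2


def _expconv(lam: float, dt: float, x: np.ndarray) -> np.ndarray:
    """exp(-lam*t) convolved with piecewise-linear x on a uniform grid.

    Exact for x linear between samples; O(n) causal recursion.
    """
    if lam * dt < 1e-12:
        # pure integration limit: trapezoidal cumulative integral
        y = np.concatenate([[0.0], np.cumsum((x[1:] + x[:-1]) * (dt / 2.0))])
        return y
    e = np.exp(-lam * dt)
    # int_0^dt exp(-lam*u) * linear(u) du split into endpoint weights
    w = (1.0 - (1.0 + lam * dt) * e) / (lam * lam * dt)  # weight of previous sample
    b1 = (1.0 - e) / lam - w  # weight of current sample
    y = signal.lfilter([b1, w], [1.0, -e], x)
    # enforce causality at t=0 (x[0] contributes nothing before any interval)
    y[0] = 0.0
    return y


def _irf_coefficients(params: KineticParams) -> tuple[float, float, float, float]:
    """Bi-exponential impulse response of C1+C2: phi1*exp(-a1 t) + phi2*exp(-a2 t)."""
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    if k3 == 0.0 and abs(k2 - k4) < 1e-9:
        # repeated eigenvalue only possible at k3=0, k2=k4; the second
        # compartment is then decoupled, so the 1T form is exact
        return K1, k2, 0.0, k2 + 1.0
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < 0:
        raise ParameterError("internal consistency error: negative eigenvalue discriminant")
    root = np.sqrt(disc)
    a1 = (s - root) / 2.0
    a2 = (s + root) / 2.0
    denom = a2 - a1
    phi1 = K1 * (k3 + k4 - a1) / denom
    phi2 = K1 * (a2 - k3 - k4) / denom
    return phi1, a1, phi2, a2


def model_2t4k(
    params: KineticParams,
    plasma: PlasmaInput,
    eval_times: np.ndarray,
    fine_dt: float = FINE_DT_MIN,
) -> np.ndarray:
    """Tissue activity C_model at ``eval_times`` (minutes)."""
    eval_times = np.asarray(eval_times, dtype=float)
    fine_t, tissue, _ = _model_fine(params, plasma, float(eval_times.max()), fine_dt)
    ct = np.interp(eval_times, fine_t, tissue)
    _, wb = plasma.sample(eval_times)
    return (1.0 - params.VB) * ct + params.VB * wb


def _model_fine(
    params: KineticParams, plasma: PlasmaInput, t_max: float, fine_dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fine grid, C1+C2 on it, whole blood on it)."""
    n = int(np.ceil(t_max / fine_dt)) + 1
    fine_t = np.arange(n) * fine_dt
    cp, wb = plasma.sample(fine_t)
    phi1, a1, phi2, a2 = _irf_coefficients(params)
    tissue = phi1 * _expconv(a1, fine_dt, cp)
    if phi2 != 0.0:
        tissue = tissue + phi2 * _expconv(a2, fine_dt, cp)
    return fine_t, tissue, wb


def frame_average(
    times: np.ndarray, curve: np.ndarray, frames: FrameSchedule
) -> np.ndarray:
    """Mean of a curve over each frame interval (trapezoidal integral / duration).

    ``times`` in minutes on a grid covering the full schedule.
    """
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(times) * (curve[1:] + curve[:-1]) / 2.0)])
    start = frames.start_s / 60.0
    end = frames.end_s / 60.0
    i_start = np.interp(start, times, cum)
    i_end = np.interp(end, times, cum)
    return (i_end - i_start) / (end - start)


def model_frame_means(
    params: KineticParams,
    plasma: PlasmaInput,
    frames: FrameSchedule,
    fine_dt: float = FINE_DT_MIN,
) -> np.ndarray:
    """Frame-averaged model output for every frame in the schedule."""
    t_max = float(frames.end_s.max()) / 60.0
    fine_t, tissue, wb = _model_fine(params, plasma, t_max, fine_dt)
    total = (1.0 - params.VB) * tissue + params.VB * wb
    return frame_average(fine_t, total, frames)


# ---------------------------------------------------------------------------
# Non-linear regression
# ---------------------------------------------------------------------------

#: parameter bounds (K1, k2, k3, k4, VB)
DEFAULT_LOWER = np.array([1e-4, 1e-4, 1e-4, 1e-4, 0.0])
DEFAULT_UPPER = np.array([2.0, 1.0, 1.0, 1.0, 0.3])


def default_starts() -> np.ndarray:
    """Eight multi-start points spanning physiological ranges.

    K1 x k2 x k3 on a 2x2x2 grid with k4 tied to the k3 level and
    VB started at 0.05.
    """
    pts = []
    for K1, k2, k3 in itertools.product((0.05, 0.3), (0.05, 0.2), (0.01, 0.1)):
        pts.append([K1, k2, k3, k3, 0.05])
    return np.array(pts)


@dataclass(frozen=True)
class FitSettings:
    """Configuration of the non-linear regression.

    Frame weights default to frame duration (uniform activity weighting).
    """

    lower: np.ndarray = field(default_factory=lambda: DEFAULT_LOWER.copy())
    upper: np.ndarray = field(default_factory=lambda: DEFAULT_UPPER.copy())
    starts: np.ndarray = field(default_factory=default_starts)
    fine_dt: float = FINE_DT_MIN
    ftol: float = 1e-9
    xtol: float = 1e-9


@dataclass
class FitResult:
    """Outcome of one regional 2T4k_VB fit."""

    params: KineticParams
    objective: float
    converged: bool
    start_index: int
    stderr: np.ndarray | None = None
    degenerate: bool = False

    @property
    def VT(self) -> float:
        return self.params.VT


def fit_2t4k(
    tac_values: np.ndarray,
    frames: FrameSchedule,
    plasma: PlasmaInput,
    weights: np.ndarray | None = None,
    settings: FitSettings | None = None,
) -> FitResult:
    """Weighted NLR of a regional TAC with the 2T4k_VB model.

    Minimises sum_f w_f * (TAC_f - frame-averaged model_f)^2 over a
    multi-start grid; returns the best converged solution.
    """
    settings = settings or FitSettings()
    y = np.asarray(tac_values, dtype=float)
    if frames.n_frames < 8:
        raise ParameterError("at least 8 frames are required for a 2T4k_VB fit")
    if y.shape != (frames.n_frames,):
        raise ParameterError("TAC length must match frame count")
    if weights is None:
        weights = frames.duration_min.copy()
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ParameterError("weights must be non-negative")
    sw = np.sqrt(weights / weights.sum())

    if np.all(y == 0):
        # non-identifiable: any K1 -> 0 fits; report the lower bound, flagged
        params = KineticParams(K1=settings.lower[0], k2=settings.lower[1], VB=0.0)
        return FitResult(
            params=params, objective=0.0, converged=True, start_index=-1,
            stderr=None, degenerate=True,
        )

    t_max = float(frames.end_s.max()) / 60.0
    n = int(np.ceil(t_max / settings.fine_dt)) + 1
    fine_t = np.arange(n) * settings.fine_dt
    cp, wb = plasma.sample(fine_t)
    wb_frames = frame_average(fine_t, wb, frames)
    fine_dt = settings.fine_dt

    def predict(x: np.ndarray) -> np.ndarray:
        p = KineticParams(*x)
        phi1, a1, phi2, a2 = _irf_coefficients(p)
        tissue = phi1 * _expconv(a1, fine_dt, cp)
        if phi2 != 0.0:
            tissue = tissue + phi2 * _expconv(a2, fine_dt, cp)
        ct = frame_average(fine_t, tissue, frames)
        return (1.0 - x[4]) * ct + x[4] * wb_frames

    def residuals(x: np.ndarray) -> np.ndarray:
        return sw * (predict(x) - y)

    best = None
    best_obj = np.inf
    best_idx = -1
    best_res = None
    for i, x0 in enumerate(settings.starts):
        x0 = np.clip(x0, settings.lower, settings.upper)
        try:
            res = optimize.least_squares(
                residuals,
                x0,
                bounds=(settings.lower, settings.upper),
                ftol=settings.ftol,
                xtol=settings.xtol,
                x_scale=np.array([0.1, 0.1, 0.05, 0.05, 0.05]),
            )
        except Exception:
            continue
        if not res.success:
            continue
        obj = 2.0 * res.cost
        if obj < best_obj:
            best, best_obj, best_idx, best_res = res, obj, i, res
    if best is None:
        raise FitError("non-linear regression failed to converge from every start")

    x = best.x
    # asymptotic standard errors from the Gauss-Newton approximation
    stderr = None
    dof = len(y) - len(x)
    if dof > 0:
        jtj = best_res.jac.T @ best_res.jac
        try:
            cov = np.linalg.pinv(jtj) * (best_obj / dof)
            stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            stderr = None
    degenerate = bool(x[0] <= settings.lower[0] * (1 + 1e-6))
    params = KineticParams(*x)
    return FitResult(
        params=params,
        objective=float(best_obj),
        converged=True,
        start_index=best_idx,
        stderr=stderr,
        degenerate=degenerate,
    )
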