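"""Endpoint statistics: regression of hippocampal on CP V_T, interaction
(slope-difference) testing between analysis conditions, and the exact
paired Wilcoxon signed-rank test.

The spill-in endpoint compares the four analysis conditions
(complete/eroded VOI x with/without PVC): if choroid-plexus spill-in
drives the apparent coupling of hippocampal and CP V_T, correcting for it
must shrink both the regression slope and r^2, the interaction term of a
stacked model ``hippo_VT ~ CP_VT * condition`` must be negative and
significant, and paired hippocampal V_T must drop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sp_stats

from .exceptions import InsufficientDataError, ParameterError

__all__ = [
    "RegressionResult",
    "InteractionResult",
    "WilcoxonResult",
    "regress_vt",
    "interaction_test",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS of hippocampal V_T on CP V_T."""

    r_squared: float
    slope: float
    intercept: float
    n: int
    p_slope: float


@dataclass(frozen=True)
class InteractionResult:
    """Slope difference between two conditions from a stacked OLS."""

    slope_difference: float
    stderr: float
    p_value: float
    conditions: tuple


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ : sum of ranks of positive differences
    p_value: float
    n_nonzero: int
    method: str
    all_zero: bool = False


def regress_vt(cp_vt: np.ndarray, hippo_vt: np.ndarray) -> RegressionResult:
    """Ordinary least squares of hippocampal V_T on CP V_T."""
    x = np.asarray(cp_vt, dtype=float)
    y = np.asarray(hippo_vt, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("cp_vt and hippo_vt must be 1D and equal length")
    if len(x) < 3:
        raise InsufficientDataError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ParameterError("degenerate regressor: CP V_T has zero variance")
    if np.ptp(y) == 0:
        # constant response: zero slope, no variance explained
        return RegressionResult(
            r_squared=0.0, slope=0.0, intercept=float(y[0]), n=len(x), p_slope=1.0
        )
    res = sp_stats.linregress(x, y)
    return RegressionResult(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(x),
        p_slope=float(res.pvalue),
    )


def interaction_test(
    table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    cp_col: str = "cp_vt",
    hippo_col: str = "hippo_vt",
    condition_col: str = "condition",
    subject_col: str = "subject",
) -> InteractionResult:
    """Slope-difference test via a stacked model hippo ~ cp * condition.

    The interaction coefficient estimates slope(B) - slope(A); its Wald
    p-value tests equality of slopes across the two conditions.
    """
    sub = table[table[condition_col].isin([condition_a, condition_b])]
    a = sub[sub[condition_col] == condition_a]
    b = sub[sub[condition_col] == condition_b]
    if len(a) < 4 or len(b) < 4:
        raise InsufficientDataError("interaction test needs n >= 4 per condition")
    if subject_col in sub.columns and set(a[subject_col]) != set(b[subject_col]):
        raise ParameterError("both conditions must cover the same subjects")
    is_b = (sub[condition_col] == condition_b).astype(float).to_numpy()
    x = sub[cp_col].to_numpy(dtype=float)
    y = sub[hippo_col].to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(x), x, is_b, x * is_b])
    fit = sm.OLS(y, design).fit()
    return InteractionResult(
        slope_difference=float(fit.params[3]),
        stderr=float(fit.bse[3]),
        p_value=float(fit.pvalues[3]),
        conditions=(condition_a, condition_b),
    )


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic W+ under random signs.

    ``ranks`` are the (mid-)ranks of the non-zero differences.  Ranks are
    doubled to integers so mid-ranks (x.5) stay exact; the null distribution
    of W+ is built by dynamic-programming convolution over sign flips.
    """
    r2 = np.round(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = 2.0 * w_plus
    lo = float(dist[: int(np.floor(w2 + 1e-9)) + 1].sum())
    hi = float(dist[int(np.ceil(w2 - 1e-9)) :].sum())
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_signed_rank(
    vt_a: np.ndarray, vt_b: np.ndarray, exact_max_n: int = 25, zero_tol: float = 0.0
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of vt_a vs vt_b (differences a - b).

    Zero differences are handled by the Pratt convention (ranked with the
    rest, then dropped from the statistic); ties get mid-ranks.  The p-value
    is exact (full sign-flip distribution) for n <= ``exact_max_n`` non-zero
    differences and uses the normal approximation with tie correction above.
    ``zero_tol`` treats differences below that fraction of the pair
    magnitude as zero (floating-point-identical pipelines).
    """
    a = np.asarray(vt_a, dtype=float)
    b = np.asarray(vt_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired vectors must be 1D and equal length")
    d = a - b
    if zero_tol > 0:
        d = np.where(np.abs(d) <= zero_tol * np.maximum(np.abs(a), np.abs(b)), 0.0, d)
    nonzero = d != 0
    n_nonzero = int(nonzero.sum())
    if n_nonzero == 0:
        return WilcoxonResult(
            statistic=0.0, p_value=1.0, n_nonzero=0, method="degenerate", all_zero=True
        )
    if n_nonzero < 5:
        raise InsufficientDataError("Wilcoxon signed-rank needs >= 5 non-zero differences")

    # Pratt: rank |d| including zeros, then drop the zeros' ranks
    ranks_all = sp_stats.rankdata(np.abs(d), method="average")
    ranks = ranks_all[nonzero]
    signs = d[nonzero] > 0
    w_plus = float(ranks[signs].sum())

    if n_nonzero <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mu = ranks.sum() / 2.0
        var = float((ranks**2).sum()) / 4.0
        if var == 0:
            p = 1.0
        else:
            z = (w_plus - mu) / np.sqrt(var)
            p = float(2.0 * sp_stats.norm.sf(abs(z)))
        method = "normal"
    return WilcoxonResult(statistic=w_plus, p_value=min(1.0, p), n_nonzero=n_nonzero, method=method)
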