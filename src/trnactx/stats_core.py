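"""Statistical primitives shared by the analysis stages.

Everything here is self-contained: rank statistics, the goodness-of-fit
chi-square, polynomial prediction with its standard error, and empirical
resampling p-values are computed directly from their definitions, with
scipy used only for reference distributions (chi-square, normal, t) and
mid-rank assignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata
from scipy.stats import t as _t

__all__ = [
    "ChiSquareResult",
    "RankSumResult",
    "CorrelationResult",
    "spearman",
    "ranksum",
    "chisq_gof",
    "polyfit_predict",
    "empirical_p",
]

# p-values are reported in (0, 1]; an exactly-zero tail probability (e.g. a
# perfectly monotone Spearman pair) is floored at the smallest positive float.
_P_FLOOR = np.nextafter(0.0, 1.0)

EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    observed: tuple[float, ...]
    expected_probs: tuple[float, ...]


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank-sum of group A (mid-ranks)
    n_a: int
    n_b: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_two_sided: float
    tie_corrected: bool
    undefined: bool = False


def _clamp_p(p: float) -> float:
    return float(min(1.0, max(_P_FLOOR, p)))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the rank vectors; the two-sided p-value
    uses the t approximation with n-2 degrees of freedom. A zero-variance
    rank vector yields an explicitly undefined result rather than NaN noise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman requires two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    rx = _rankdata(x)
    ry = _rankdata(y)
    tie_corrected = (np.unique(x).size < n) or (np.unique(y).size < n)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(math.nan, n, math.nan, tie_corrected, undefined=True)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = _P_FLOOR
    else:
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = _clamp_p(2.0 * float(_t.sf(abs(tstat), n - 2)))
    return CorrelationResult(rho, n, p, tie_corrected)


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided exact p by full enumeration of group labelings.

    Enumerates all C(n, n_a) assignments of the pooled mid-ranks to group A;
    ties are handled implicitly because the enumeration runs over the observed
    pooled multiset. Two-sided p = 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    n = ranks.size
    total = math.comb(n, n_a)
    le = ge = 0
    eps = 1e-9
    for combo in itertools.combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return _clamp_p(2.0 * min(le, ge) / total)


def ranksum(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    With ``method='auto'``: exact enumeration for pooled n <= 12, otherwise
    the normal approximation with mid-rank tie correction and a 0.5
    continuity correction. ``'exact'`` / ``'normal_approx'`` force a path.
    """
    if method not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ranksum requires two non-empty groups")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = _rankdata(pooled)
    w = float(ranks[:n_a].sum())
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_RANKSUM_MAX_N)
    if use_exact:
        if n > 2 * EXACT_RANKSUM_MAX_N:
            raise ValueError("exact enumeration is limited to small samples")
        p = _exact_ranksum_p(ranks, n_a, w)
        return RankSumResult(w, n_a, n_b, p, "exact")
    mean = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1)))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return RankSumResult(w, n_a, n_b, 1.0, "normal_approx")
    # continuity correction pulls |W - mean| toward the null mean
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = _clamp_p(2.0 * float(_norm.sf(z)))
    return RankSumResult(w, n_a, n_b, p, "normal_approx")


def chisq_gof(
    observed: Sequence[float], expected_probs: Sequence[float]
) -> ChiSquareResult:
    """Goodness-of-fit chi-square of observed counts against cell probabilities."""
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and expected_probs must be equal-length vectors")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    if not math.isclose(probs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("expected probabilities must sum to 1")
    total = obs.sum()
    expected = total * probs
    if np.any(expected == 0):
        raise ValueError("degenerate null: an expected count is zero")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = _clamp_p(float(_chi2.sf(stat, df)))
    return ChiSquareResult(stat, df, p, tuple(obs), tuple(probs))


def polyfit_predict(
    x: Sequence[float],
    y: Sequence[float],
    degree: int,
    x0: float,
) -> tuple[np.ndarray, float, float]:
    """Ordinary least-squares polynomial fit with the prediction SE at x0.

    Returns (coefficients in ascending powers, fitted value at x0, standard
    error of the mean prediction at x0). The SE comes from the fit covariance
    s^2 (X'X)^-1 with residual variance s^2 = RSS / (n - degree - 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    n_distinct = np.unique(x).size
    if n_distinct < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct x values, got {n_distinct}"
        )
    design = np.vander(x, degree + 1, increasing=True)
    coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise ValueError("rank-deficient design matrix")
    resid = y - design @ coeffs
    dof = n - degree - 1
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    xtx_inv = np.linalg.inv(design.T @ design)
    v0 = np.power(x0, np.arange(degree + 1), dtype=float)
    value = float(v0 @ coeffs)
    se = float(math.sqrt(max(0.0, s2 * float(v0 @ xtx_inv @ v0))))
    return coeffs, value, se


def empirical_p(
    observed: float, resample_stats: Sequence[float], tail: str = "lower"
) -> float:
    """Resampling p-value (r+1)/(N+1); ties count as extreme, floor 1/(N+1)."""
    stats = np.asarray(resample_stats, dtype=float)
    if stats.size < 1:
        raise ValueError("need at least one resample statistic")
    if tail == "lower":
        r = int((stats <= observed).sum())
    elif tail == "upper":
        r = int((stats >= observed).sum())
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return (r + 1) / (stats.size + 1)
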