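"""Exact small-sample statistical tests used across the toolkit.

Implements the Mann-Whitney U test (exact permutation null for small
untied samples), the one-sample Wilcoxon signed-rank test against zero
(exact sign-flip null for small samples), Benjamini-Hochberg step-up
adjustment, and the chi-squared goodness-of-fit test with optional Yates
continuity correction. Exact enumerations are dynamic-programming
convolutions, not Monte Carlo, so p-values are reproducible to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import polygamma

__all__ = [
    "StatResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank_vs_zero",
    "bh_adjust",
    "chi_squared_gof",
]

# switchover sizes beyond which enumeration gives way to the normal
# approximation (with tie and continuity corrections)
MWU_EXACT_MAX_N = 20
WILCOXON_EXACT_MAX_N = 15


@dataclass
class StatResult:
    """Outcome of a hypothesis test."""

    name: str
    statistic: float
    p_value: float
    method: str  # "exact" or "normal-approximation"
    n: tuple[int, ...]
    df: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")
        self.p_value = float(min(self.p_value, 1.0))


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """Number of size-n1 subsets of ranks 1..n1+n2 for each rank-sum.

    counts[s] = #subsets with sum s; classic subset-sum DP.
    """
    n = n1 + n2
    max_sum = n * (n + 1) // 2
    # ways[k][s] -> ways to choose k ranks summing to s
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            ways[k, r:] += ways[k - 1, :-r] if r > 0 else ways[k - 1, :]
    return ways[n1]


def mann_whitney_u(x, y) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact when ``len(x)+len(y) <= 20`` and there are no ties across the
    pooled sample; otherwise a normal approximation with midrank tie
    correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires two non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # U of sample x
    n12 = n1 * n2

    has_ties = np.unique(pooled).size < pooled.size
    if (n1 + n2) <= MWU_EXACT_MAX_N and not has_ties:
        counts = _rank_sum_counts(n1, n2)
        total = counts.sum()
        # U = R1 - n1(n1+1)/2 takes integer values 0..n1*n2
        offset = n1 * (n1 + 1) // 2
        u_counts = counts[offset : offset + n12 + 1]
        u_obs = int(round(u1))
        m = min(u_obs, n12 - u_obs)
        p = (u_counts[: m + 1].sum() + u_counts[n12 - m :].sum()) / total
        if m == n12 - m:  # the two tails coincide at the centre
            p = min(p, 1.0)
        return StatResult("mann-whitney U", float(u1), float(min(p, 1.0)),
                          "exact", (n1, n2))

    mu = n12 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n12 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return StatResult("mann-whitney U", float(u1), 1.0,
                          "normal-approximation", (n1, n2))
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return StatResult("mann-whitney U", float(u1), float(min(p, 1.0)),
                      "normal-approximation", (n1, n2))


def _signed_rank_counts(double_ranks: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all 2^n sign assignments.

    ``double_ranks`` are midranks multiplied by 2 (hence integers even
    with ties). counts[s] = #assignments with doubled positive-rank sum s.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_vs_zero(d) -> StatResult:
    """Two-sided one-sample Wilcoxon signed-rank test of median zero.

    Exact zeros are dropped first. Exact null by enumerating the 2^n sign
    assignments for n <= 15, else normal approximation with tie and
    continuity corrections. If every value is zero the result is the
    degenerate p = 1 flagged in ``extra``.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("wilcoxon_signed_rank_vs_zero requires data")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return StatResult("wilcoxon signed-rank", 0.0, 1.0, "degenerate",
                          (0,), extra={"all_zero": True})
    n = nonzero.size
    ranks = _midranks(np.abs(nonzero))
    w_plus = ranks[nonzero > 0].sum()
    total = n * (n + 1) / 2.0

    if n <= WILCOXON_EXACT_MAX_N:
        dbl = np.round(2 * ranks)
        counts = _signed_rank_counts(dbl)
        denom = counts.sum()  # 2^n
        w2 = int(round(2 * w_plus))
        tot2 = int(round(2 * total))
        m = min(w2, tot2 - w2)
        p = (counts[: m + 1].sum() + counts[tot2 - m :].sum()) / denom
        if m == tot2 - m:
            p = min(p, 1.0)
        return StatResult("wilcoxon signed-rank", float(w_plus),
                          float(min(p, 1.0)), "exact", (n,))

    mu = total / 2.0
    _, tie_counts = np.unique(np.abs(nonzero), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (abs(w_plus - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return StatResult("wilcoxon signed-rank", float(w_plus),
                      float(min(p, 1.0)), "normal-approximation", (n,))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def chi_squared_gof(observed, expected_props, yates: bool = False) -> StatResult:
    """Chi-squared goodness-of-fit test against expected proportions.

    With ``yates=True`` (permitted only for 2 cells, i.e. 1 df) each
    cell's |O - E| is reduced by 0.5, floored at zero so small deviations
    are never over-corrected.
    """
    observed = np.asarray(observed, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if observed.shape != props.shape:
        raise ValueError("observed and expected_props must have equal length")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    if yates and observed.size != 2:
        raise ValueError("Yates correction applies to 2 cells only")
    expected = props * observed.sum()
    if np.any(expected <= 0):
        raise ValueError("every expected count must be positive")
    dev = np.abs(observed - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev**2 / expected))
    df = observed.size - 1
    p = float(sps.chi2.sf(statistic, df))
    return StatResult("chi-squared GOF" + (" (Yates)" if yates else ""),
                      statistic, p, "chi2", (int(observed.sum()),), df=df)


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Used by the moderated paired test to estimate the prior degrees of
    freedom from the spread of log sample variances.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)
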