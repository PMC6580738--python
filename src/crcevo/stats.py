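"""Statistical machinery used by the cohort comparisons.

Self-contained implementations with the conventions pinned down
explicitly, so that downstream results do not drift with library
defaults:

* Fisher's exact 2x2 test, two-sided by the point-probability
  ("minimum-likelihood") rule: the p-value sums hypergeometric point
  probabilities no larger than that of the observed table.
* Benjamini-Hochberg step-up false-discovery-rate adjustment.
* Mann-Whitney U, exact by full enumeration of group assignments for
  small samples (n_x + n_y <= 12), otherwise a tie-corrected normal
  approximation with continuity correction.
* Kruskal-Wallis H with tie correction and a chi-square reference
  distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "bh_adjust",
    "mann_whitney_u",
    "kruskal_wallis",
]

EXACT_MWU_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    The odds ratio is the sample odds ratio a*d / (b*c); it is ``inf``
    when b*c == 0 with a*d > 0 and ``nan`` for doubly degenerate tables.
    Degenerate tables (an empty row or column margin) have p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        odds = math.nan
        return TestResult(odds, 1.0, "fisher_exact", exact=True)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)

    # Support of a given fixed margins.
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(ks, n, c1, r1)
    p_obs = pmf[a - lo]
    # Relative tolerance guards against ties broken by rounding error.
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return TestResult(odds, min(p, 1.0), "fisher_exact", exact=True)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * n / j over the sorted p-values, capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: number of (x_i, y_j) pairs with x_i > y_j, ties 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For n_x + n_y <= 12 the null distribution of U is built by full
    enumeration of the C(n, n_x) group assignments of the pooled values
    (so ties are handled exactly); the two-sided p-value is
    P(U <= u_min) + P(U >= n_x n_y - u_min) with u_min the smaller of
    the two one-sided statistics.  Larger samples use the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    u = _u_statistic(x, y)
    nxny = nx * ny
    if nx + ny <= EXACT_MWU_MAX_N:
        pooled = np.concatenate([x, y])
        idx = range(nx + ny)
        u_min = min(u, nxny - u)
        count = 0
        total = 0
        for comb in combinations(idx, nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u_perm <= u_min + 1e-12 or u_perm >= nxny - u_min - 1e-12:
                count += 1
        p = count / total
        return TestResult(u, min(p, 1.0), "mann_whitney_u", exact=True)

    # Normal approximation with tie correction and continuity correction.
    pooled = np.concatenate([x, y])
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nxny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(u, 1.0, "mann_whitney_u", exact=False)
    mu = nxny / 2.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(u, min(p, 1.0), "mann_whitney_u", exact=False)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups, tie-corrected, with the
    chi-square (k-1 df) reference distribution."""
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    offset = 0
    for a in arrays:
        r = ranks[offset : offset + a.size]
        h += r.sum() ** 2 / a.size
        offset += a.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0:
        # All observations identical: no evidence against the null.
        return TestResult(0.0, 1.0, "kruskal_wallis", exact=False)
    h /= correction
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h, df)) if h > 0 else 1.0
    return TestResult(h, min(p, 1.0), "kruskal_wallis", exact=False)
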