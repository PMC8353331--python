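"""Exact statistical tests for small-cohort marker comparisons.

Two tests cover everything the marker analyses need: the two-sided Fisher
exact test on 2x2 tables (categorical features, e.g. marker positivity by
response group) and the two-sided Mann-Whitney U test (continuous features,
e.g. signature exposures, TMB).  Both are implemented here rather than
delegated so that the exact conventions are fixed and documented:

* Fisher's two-sided p uses the probability-mass definition -- the sum of
  hypergeometric probabilities of every table with the observed margins whose
  probability does not exceed that of the observed table (a small relative
  tolerance absorbs floating-point ties).  This is the convention of R's
  ``fisher.test`` and reproduces textbook tables.
* Mann-Whitney uses the exact permutation distribution of U for small
  tie-free samples (total n <= 20) and a tie-corrected, continuity-corrected
  normal approximation otherwise.

p-values are exact probabilities in [0, 1]; formatting to the conventional
three decimal places lives in :mod:`platmark.report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "Table2x2",
    "TestResult",
    "hypergeom_pmf",
    "fisher_exact_two_sided",
    "mann_whitney_u",
    "benjamini_hochberg",
]

#: relative tolerance used to absorb floating-point ties between table
#: probabilities in the two-sided Fisher sum
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 contingency table: rows = groups, columns = feature yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"table entry {name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "fisher_exact" | "mann_whitney"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf(x: int, n_total: int, n_success: int, n_draw: int) -> float:
    """P[X = x] for a hypergeometric draw, computed in log-space.

    ``n_draw`` items are drawn without replacement from ``n_total`` items of
    which ``n_success`` are successes; returns the probability of seeing
    exactly ``x`` successes (0 outside the support).
    """
    if not (0 <= n_success <= n_total):
        raise ValueError(f"need 0 <= n_success <= n_total, got {n_success}, {n_total}")
    if not (0 <= n_draw <= n_total):
        raise ValueError(f"need 0 <= n_draw <= n_total, got {n_draw}, {n_total}")
    lo = max(0, n_draw - (n_total - n_success))
    hi = min(n_draw, n_success)
    if x < lo or x > hi:
        return 0.0
    return math.exp(
        _log_binom(n_success, x)
        + _log_binom(n_total - n_success, n_draw - x)
        - _log_binom(n_total, n_draw)
    )


def fisher_exact_two_sided(table: Table2x2) -> TestResult:
    """Two-sided Fisher exact test (probability-mass definition).

    The statistic reported is the sample odds ratio (``inf`` when the
    denominator product is zero and the numerator is not).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    row1 = a + b
    col1 = a + c
    p_obs = hypergeom_pmf(a, n, col1, row1)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    cutoff = p_obs * (1.0 + _FISHER_REL_TOL)
    p = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom_pmf(x, n, col1, row1)
        if px <= cutoff:
            p += px
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(statistic=odds, p_value=min(p, 1.0), method="fisher_exact")


def _exact_u_distribution(n_x: int, n_y: int) -> np.ndarray:
    """Counts of rank-sum values for all C(n, n_x) assignments (no ties).

    Dynamic programme over ranks 1..n choosing which go to sample x; entry
    ``counts[s]`` is the number of assignments whose x rank-sum is ``s``.
    """
    n = n_x + n_y
    max_sum = n_x * n + 1
    # counts[k][s]: subsets of size k with rank-sum s
    counts = np.zeros((n_x + 1, max_sum), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n_x), 0, -1):
            counts[k, r:] += counts[k - 1, :-r] if r > 0 else counts[k - 1]
    return counts[n_x]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U is computed from midranks for the first sample.  With ``method="auto"``
    the p-value is exact (full enumeration of the permutation distribution of
    U via a rank-sum dynamic programme) for combined sample sizes <= 20 with
    no ties, and otherwise a normal approximation with tie correction and
    continuity correction.  ``method="exact"``/``"asymptotic"`` force a path
    (exact requires tie-free data).
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r_x = float(ranks[:n_x].sum())
    u_x = r_x - n_x * (n_x + 1) / 2.0
    mu = n_x * n_y / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    use_exact = (n <= 20 and not has_ties) if method == "auto" else method == "exact"
    if use_exact and has_ties:
        raise ValueError("exact method requires tie-free samples")
    if use_exact:
        dist = _exact_u_distribution(n_x, n_y)
        total = dist.sum()
        sums = np.arange(dist.size, dtype=float)
        u_all = sums - n_x * (n_x + 1) / 2.0
        # two-sided: tables at least as far from the null mean as observed
        extreme = np.abs(u_all - mu) >= abs(u_x - mu) - 1e-9
        p = float(dist[extreme].sum() / total)
    else:
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all observations identical
            return TestResult(statistic=u_x, p_value=1.0, method="mann_whitney")
        diff = abs(u_x - mu) - 0.5  # continuity correction toward the mean
        z = max(diff, 0.0) / math.sqrt(var)
        p = float(2.0 * (1.0 - 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))))
    return TestResult(statistic=u_x, p_value=min(p, 1.0), method="mann_whitney")


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; no correction is
    applied by default anywhere in the pipeline)."""
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m, dtype=float)
    running_min = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running_min = min(running_min, p[i] * m / (rank_idx + 1))
        adjusted[i] = running_min
    return adjusted
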