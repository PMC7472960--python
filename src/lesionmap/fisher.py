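"""Two-tailed Fisher's exact test on 2x2 voxel contingency tables.

At each voxel the cohort splits into a 2x2 table: ``a`` patients of
phenotype A with tumour at the voxel, ``b`` of phenotype B with tumour,
``c`` and ``d`` the corresponding tumour-free counts, ``n = a+b+c+d``.
Under the null of no association the table follows the hypergeometric
distribution with fixed margins, whose point probability is

    P(a,b,c,d) = (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! n!)

The two-sided p value is the "method of small p-values": the sum of the
point probabilities of every table with the same margins whose probability
does not exceed the observed one (within a small relative tolerance to
absorb floating-point ties). Everything is evaluated in log space via
log-gamma for stability at cohort sizes in the thousands.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContingencyTable",
    "voxel_contingency",
    "hypergeometric_point_probability",
    "fisher_exact_two_tailed",
]

#: relative tolerance when classifying "as or more extreme" tables
TIE_RELTOL = 1e-7


class ContingencyTable(NamedTuple):
    a: int  # phenotype A, tumour at voxel
    b: int  # phenotype B, tumour at voxel
    c: int  # phenotype A, tumour-free
    d: int  # phenotype B, tumour-free

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_a(self) -> int:
        return self.a + self.c

    @property
    def n_b(self) -> int:
        return self.b + self.d


def _validate(t: ContingencyTable) -> None:
    if min(t) < 0:
        raise ValueError(f"negative contingency entries: {t}")
    if t.n < 1:
        raise ValueError("empty contingency table")


def voxel_contingency(
    count_a: int, n_a: int, count_b: int, n_b: int
) -> ContingencyTable:
    """Assemble the per-voxel 2x2 table from group occupancy counts."""
    if not (0 <= count_a <= n_a):
        raise ValueError(f"count_a={count_a} outside [0, {n_a}]")
    if not (0 <= count_b <= n_b):
        raise ValueError(f"count_b={count_b} outside [0, {n_b}]")
    return ContingencyTable(count_a, count_b, n_a - count_a, n_b - count_b)


def _log_support(t: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Log point probabilities over all tables sharing ``t``'s margins.

    Tables are indexed by the ``a`` cell; returns (a values, log pmf).
    """
    n_a, n_b, m = t.n_a, t.n_b, t.a + t.b
    lo, hi = max(0, m - n_b), min(m, n_a)
    k = np.arange(lo, hi + 1)

    def lchoose(n, x):
        return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)

    logp = lchoose(n_a, k) + lchoose(n_b, m - k) - lchoose(t.n, m)
    return k, logp


def hypergeometric_point_probability(t: ContingencyTable) -> float:
    """Exact probability of one table under fixed margins."""
    t = ContingencyTable(*t)
    _validate(t)
    k, logp = _log_support(t)
    return float(np.exp(logp[t.a - k[0]]))


def fisher_exact_two_tailed(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of all as-or-less-probable tables.

    The p value is invariant under swapping the two groups and under
    swapping the occupied/free rows; tables are canonicalised over those
    symmetries before evaluation, so the invariance holds exactly (and the
    memoisation cache collapses equivalent tables).
    """
    t = ContingencyTable(*t)
    _validate(t)
    a, b, c, d = t
    key = min((a, b, c, d), (b, a, d, c), (c, d, a, b), (d, c, b, a))
    return _fisher_cached(*key)


@lru_cache(maxsize=None)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    t = ContingencyTable(a, b, c, d)
    k, logp = _log_support(t)
    observed = logp[a - k[0]]
    keep = logp <= observed + np.log1p(TIE_RELTOL)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def fisher_cache_info():
    """Memoisation statistics (distinct tables evaluated so far)."""
    return _fisher_cached.cache_info()
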