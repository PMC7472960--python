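"""Independent brute-force oracles, kept deliberately separate from the
implementation paths they check: exact integer arithmetic for Fisher's test,
naive summation for frequency maps."""

from fractions import Fraction
from math import comb

import numpy as np

# classification tolerance shared with the two-sided definition (a table is
# "as extreme" when its probability <= observed * (1 + 1e-7)); applied here
# in exact integer arithmetic
_TOL_NUM, _TOL_DEN = 10**7 + 1, 10**7


def fisher_two_tailed_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over integer weights.

    The point probability of the table with first cell k is proportional to
    C(nA, k) * C(nB, m - k); comparisons and the final sum are exact
    (integers / Fraction), independent of the log-gamma implementation.
    """
    n_a, n_b, m = a + c, b + d, a + b
    lo, hi = max(0, m - n_b), min(m, n_a)
    weights = {k: comb(n_a, k) * comb(n_b, m - k) for k in range(lo, hi + 1)}
    observed = weights[a]
    numerator = sum(
        w for w in weights.values() if w * _TOL_DEN <= observed * _TOL_NUM
    )
    return float(Fraction(numerator, comb(n_a + n_b, m)))


def point_probability_exact(a: int, b: int, c: int, d: int) -> float:
    n_a, n_b, m = a + c, b + d, a + b
    return float(
        Fraction(comb(n_a, a) * comb(n_b, b), comb(n_a + n_b, m))
    )


def frequency_counts_naive(masks) -> np.ndarray:
    """Per-voxel overlap count by per-voxel python loops (tiny grids only)."""
    shape = masks[0].occupancy.shape
    counts = np.zeros(shape, dtype=int)
    for idx in np.ndindex(shape):
        counts[idx] = sum(int(m.occupancy[idx]) for m in masks)
    return counts
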