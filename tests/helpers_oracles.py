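"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain loops, sets and
library routines (scipy/statsmodels) so that each metric is checked by two
unrelated routes.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


def pearson_oracle(x, y) -> float:
    """Pearson correlation via scipy (independent of the package's moments)."""
    return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic)


def slope_oracle(y, x) -> float:
    """OLS slope via scipy.linregress."""
    return float(stats.linregress(np.asarray(x, float), np.asarray(y, float)).slope)


def nodf_bruteforce(matrix: np.ndarray) -> float:
    """Straightforward pairwise NODF recomputation with loops and sets.

    Drops empty rows/columns, sorts by decreasing degree, then scores every
    ordered pair: 0 unless the lower member has strictly smaller degree, in
    which case the pair scores the percentage of the lower member's
    partners shared with the upper member.
    """
    a = np.asarray(matrix)
    a = a[a.sum(axis=1) > 0][:, a.sum(axis=0) > 0]
    total = 0.0
    for mat in (a, a.T):
        rows = sorted(
            (set(np.flatnonzero(r)) for r in mat), key=len, reverse=True
        )
        for upper, lower in combinations(rows, 2):
            if len(lower) < len(upper) and len(lower) > 0:
                total += 100.0 * len(lower & upper) / len(lower)
    m, f = a.shape
    denom = m * (m - 1) / 2 + f * (f - 1) / 2
    return total / denom if denom else 0.0


def sci_bruteforce(matrix: np.ndarray, male: int) -> float:
    """Harmonic mean of one male's partner degrees, by direct summation."""
    a = np.asarray(matrix)
    partners = np.flatnonzero(a[male])
    shares = [1.0 / a[:, j].sum() for j in partners]
    return len(partners) / sum(shares)


def count_constrained_matrices(m: int, f: int, e: int) -> int:
    """Number of m x f binary matrices with e ones and no empty row/column,
    by inclusion-exclusion over empty rows and columns."""
    total = 0
    for a in range(m + 1):
        for b in range(f + 1):
            total += (
                (-1) ** (a + b)
                * math.comb(m, a)
                * math.comb(f, b)
                * math.comb((m - a) * (f - b), e)
            )
    return total


def count_uniform_column_matrices(m: int, f: int, col_sum: int) -> int:
    """Number of m x f binary matrices with every column sum equal to
    ``col_sum`` and no empty row, by inclusion-exclusion over empty rows."""
    total = 0
    for a in range(m + 1):
        total += (-1) ** a * math.comb(m, a) * math.comb(m - a, col_sum) ** f
    return total


def degenerate_probability(m: int, f: int, e: int) -> float:
    """P(all column sums equal) for a uniform constrained matrix draw.

    With e ones over f columns, equal column sums force each to e / f;
    impossible unless f divides e.
    """
    if e % f != 0:
        return 0.0
    return count_uniform_column_matrices(m, f, e // f) / count_constrained_matrices(
        m, f, e
    )
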