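"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: exact rational
arithmetic via fractions and direct enumeration over subsets.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats as sps


def binomial_upper_tail_exact(k: int, n: int, p0_num: int, p0_den: int) -> Fraction:
    """P(X >= k), X ~ Binomial(n, p0_num/p0_den), as an exact rational."""
    p = Fraction(p0_num, p0_den)
    q = 1 - p
    return sum(
        (comb(n, j) * p**j * q ** (n - j) for j in range(k, n + 1)),
        Fraction(0),
    )


def hypergeom_tail_by_enumeration(n_universe: int, size_a: int, size_b: int):
    """Exact P(X >= k) for every attainable overlap k, by subset enumeration.

    Enumerates all C(N, size_a) draws of set A against a fixed B (the low
    ``size_b`` bits of a bitmask) and counts overlaps.  Returns a dict
    {k: Fraction}.
    """
    b_mask = (1 << size_b) - 1
    counts: dict[int, int] = {}
    total = 0
    for mask in range(1 << n_universe):
        if mask.bit_count() != size_a:
            continue
        total += 1
        k = (mask & b_mask).bit_count()
        counts[k] = counts.get(k, 0) + 1
    tails = {}
    for k in range(0, min(size_a, size_b) + 1):
        tails[k] = Fraction(sum(v for kk, v in counts.items() if kk >= k), total)
    return tails


def bh_stepup_reference(pvals: np.ndarray) -> np.ndarray:
    """Reference Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def pearson_reference(x: np.ndarray, y: np.ndarray):
    """Pearson r and two-sided p via the direct covariance/SD formula and
    the t transform with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p)
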