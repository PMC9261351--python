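"""Statistical primitives: binomial consensus p-value, hypergeometric overlap
with odds ratio, Benjamini-Hochberg adjustment, and Pearson fold-change
correlation.

The consensus p-value (CPV) for a gene is the upper-tail binomial probability
of observing at least k nominally significant differential-expression calls
out of the n experiments in which the gene was assayed, under a per-experiment
null success probability p0 (0.05 by default):

    CPV(k, n) = sum_{j=k}^{n} C(n, j) p0^j (1 - p0)^(n - j)

Gene-set overlaps are scored with the one-sided (enrichment) hypergeometric
tail P(X >= k) and the cross-product odds ratio of the 2x2 overlap table,
with a Haldane-Anscombe 0.5 correction applied to every cell when any cell
is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "binomial_cpv",
    "bh_adjust",
    "hypergeom_overlap",
    "OverlapResult",
    "fc_correlation",
    "CorrelationResult",
]


def binomial_cpv(k: int, n: int, p0: float = 0.05) -> float:
    """Upper-tail binomial probability P(X >= k) for X ~ Binomial(n, p0).

    Parameters
    ----------
    k : int
        Number of experiments with a nominally significant call.
    n : int
        Number of experiments in which the gene was assayed.
    p0 : float
        Null per-experiment success probability (the nominal alpha).

    Returns
    -------
    float
        The consensus p-value, in (0, 1]; 1.0 when k == 0.
    """
    if not 0 < p0 < 1:
        raise InputError(f"p0 must be in (0, 1), got {p0}")
    if k < 0 or n < 0 or k > n:
        raise InputError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); survival function keeps the tail accurate.
    return float(sps.binom.sf(k - 1, n, p0))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap between two sets within a finite universe."""

    k: int
    size_a: int
    size_b: int
    universe_size: int
    odds_ratio: float
    pvalue: float
    degenerate: bool  # True when the Haldane-Anscombe correction was applied

    @property
    def table(self) -> tuple[int, int, int, int]:
        """The 2x2 table (a&b, a-only, b-only, neither)."""
        return (
            self.k,
            self.size_a - self.k,
            self.size_b - self.k,
            self.universe_size - self.size_a - self.size_b + self.k,
        )


def hypergeom_overlap(
    set_a: Collection[str],
    set_b: Collection[str],
    universe: Collection[str],
) -> OverlapResult:
    """One-sided enrichment test for the overlap of two gene (or node) sets.

    Tests whether |set_a & set_b| is larger than expected when drawing
    |set_a| items without replacement from a universe containing |set_b|
    marked items: pvalue = P(X >= k), X ~ Hypergeom(N, |set_b|, |set_a|).

    The odds ratio is the cross-product ratio of the overlap 2x2 table; when
    any cell is zero, 0.5 is added to every cell (Haldane-Anscombe) and the
    result is flagged as degenerate.
    """
    uni = frozenset(universe)
    if not uni:
        raise InputError("empty universe")
    a = frozenset(set_a)
    b = frozenset(set_b)
    if not a <= uni:
        raise InputError(f"set_a has {len(a - uni)} members outside the universe")
    if not b <= uni:
        raise InputError(f"set_b has {len(b - uni)} members outside the universe")
    n_uni = len(uni)
    k = len(a & b)
    pvalue = float(sps.hypergeom.sf(k - 1, n_uni, len(b), len(a))) if k > 0 else 1.0
    pvalue = min(pvalue, 1.0)
    cells = np.array(
        [k, len(a) - k, len(b) - k, n_uni - len(a) - len(b) + k], dtype=float
    )
    degenerate = bool(np.any(cells == 0))
    if degenerate:
        cells = cells + 0.5
    odds_ratio = float(cells[0] * cells[3] / (cells[1] * cells[2]))
    return OverlapResult(
        k=k,
        size_a=len(a),
        size_b=len(b),
        universe_size=n_uni,
        odds_ratio=odds_ratio,
        pvalue=pvalue,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with adjusted r-squared on a gene subset."""

    r: float
    r2: float
    adj_r2: float
    pvalue: float
    n: int


def fc_correlation(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
) -> CorrelationResult:
    """Pearson correlation between two paired fold-change vectors.

    Returns r, r^2, the adjusted r^2 = 1 - (1 - r^2)(n - 1)/(n - 2) for a
    single-predictor fit, and the two-sided p-value from the t transform with
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise InputError(f"need at least 3 paired values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined: zero variance in input vector")
    r, pvalue = sps.pearsonr(x, y)
    r = float(r)
    r2 = r * r
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CorrelationResult(r=r, r2=r2, adj_r2=adj_r2, pvalue=float(pvalue), n=n)
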