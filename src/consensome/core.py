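"""Consensome construction: consensus ranking of genes across a compendium of
differential-expression contrasts.

For each gene the algorithm counts the number of assayed contrasts in which
the gene is nominally significant (p < alpha, strictly), computes the binomial
consensus p-value (CPV) of seeing at least that many successes given a null
per-contrast rate p0, adjusts CPVs across genes by Benjamini-Hochberg to give
consensus q-values (CQV), and averages log2 fold changes over assayed
contrasts to give the log2 geometric mean fold change (GMFC, reported on the
log2 scale).  Genes are ranked by CPV ascending, ties broken by |GMFC|
descending, then by gene id; percentiles follow from rank.  Confidence
transcript sets are the induced (CQV < q_max, GMFC > lfc_min) and repressed
(CQV < q_max, GMFC < -lfc_min) tails.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import fmt_float
from .datatypes import ContrastTable
from .errors import InputError
from .stats import bh_adjust, binomial_cpv

__all__ = [
    "count_significant",
    "gmfc",
    "percentile_of_rank",
    "build_consensome",
    "designate_confidence_sets",
    "ConsensomeModel",
    "ConsensomeResults",
]

logger = logging.getLogger(__name__)

CONSENSOME_COLUMNS = [
    "gene_id",
    "n_sig",
    "n_assayed",
    "cpv",
    "cqv",
    "gmfc_log2",
    "rank",
    "percentile",
    "is_induced_ct",
    "is_repressed_ct",
]


def count_significant(
    pvalues: Sequence[float],
    assayed: Sequence[bool] | None = None,
    alpha: float = 0.05,
) -> tuple[int, int]:
    """Count nominally significant calls for one gene across contrasts.

    Returns ``(k, n)`` where n is the number of assayed contrasts and k the
    number of those with p strictly below alpha (p == alpha is not counted).
    """
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(pvalues, dtype=float)
    mask = (
        np.ones(p.shape, dtype=bool)
        if assayed is None
        else np.asarray(assayed, dtype=bool)
    )
    n = int(mask.sum())
    if n == 0:
        raise InputError("gene assayed in zero contrasts")
    k = int((p[mask] < alpha).sum())
    return k, n


def gmfc(log2fcs: Sequence[float]) -> float:
    """Log2 geometric mean fold change: the mean of log2 fold changes.

    Equals log2 of the geometric mean of |FC| with the sign carried by the
    mean; reported on the log2 scale.
    """
    x = np.asarray(log2fcs, dtype=float)
    if x.size == 0:
        raise InputError("gmfc of empty list")
    if not np.all(np.isfinite(x)):
        raise InputError("gmfc requires finite log2 fold changes")
    return float(x.mean())


def percentile_of_rank(rank: int, n_total: int) -> float:
    """Exact percentile of a 1-based rank: 100 * (n_total - rank) / n_total.

    The top-ranked item of 100 sits at 99.0; the bottom at 0.0.  Display
    formatting floors this to an integer; the exact rational is kept here.
    """
    if not 1 <= rank <= n_total:
        raise InputError(f"rank must be in [1, {n_total}], got {rank}")
    return 100.0 * (n_total - rank) / n_total


def build_consensome(
    compendium: Iterable[ContrastTable],
    alpha: float = 0.05,
    p0: float = 0.05,
    q_max: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Build the consensome table from a compendium of contrasts.

    Parameters
    ----------
    compendium : iterable of ContrastTable
        The differential-expression contrasts; gene universes may overlap
        partially.  Genes assayed in zero contrasts are dropped (logged).
    alpha : float
        Per-contrast nominal significance threshold (strict).
    p0 : float
        Null success probability of the binomial consensus model.  Plays a
        different role from ``alpha`` (call threshold vs null rate) even
        though both default to 0.05.
    q_max, lfc_min : float
        Confidence-transcript thresholds (see
        :func:`designate_confidence_sets`).

    Returns
    -------
    pandas.DataFrame
        One row per retained gene with columns ``gene_id, n_sig, n_assayed,
        cpv, cqv, gmfc_log2, rank, percentile, is_induced_ct,
        is_repressed_ct``, sorted by rank.
    """
    contrasts = list(compendium)
    if not contrasts:
        raise InputError("empty compendium")
    if not 0 < alpha < 1 or not 0 < p0 < 1:
        raise InputError("alpha and p0 must be in (0, 1)")

    # Wide per-contrast frames indexed by gene.
    frames_p, frames_lfc, frames_assay = [], [], []
    for ct in contrasts:
        d = ct.data.set_index("gene_id")
        frames_assay.append(d["assayed"].astype(bool).rename(ct.contrast_id))
        frames_p.append(d["pvalue"].rename(ct.contrast_id))
        frames_lfc.append(d["log2fc"].rename(ct.contrast_id))
    assayed = pd.concat(frames_assay, axis=1).fillna(False)
    pmat = pd.concat(frames_p, axis=1)
    lmat = pd.concat(frames_lfc, axis=1)

    amask = assayed.to_numpy(dtype=bool)
    n_assayed = amask.sum(axis=1)
    dropped = int((n_assayed == 0).sum())
    if dropped:
        logger.info("dropping %d genes assayed in zero contrasts", dropped)
    keep = n_assayed > 0

    pv = pmat.to_numpy(dtype=float)
    lf = lmat.to_numpy(dtype=float)
    sig = (pv < alpha) & amask
    n_sig = sig.sum(axis=1)

    genes = assayed.index.to_numpy()[keep]
    n = n_assayed[keep]
    k = n_sig[keep]
    with np.errstate(invalid="ignore"):
        mean_lfc = np.where(amask, lf, 0.0).sum(axis=1)[keep] / n

    cpv = sps.binom.sf(k - 1, n, p0)
    cpv = np.where(k == 0, 1.0, cpv)
    cqv = bh_adjust(cpv)

    table = pd.DataFrame(
        {
            "gene_id": genes,
            "n_sig": k.astype(int),
            "n_assayed": n.astype(int),
            "cpv": cpv,
            "cqv": cqv,
            "gmfc_log2": mean_lfc,
        }
    )
    table = _sort_consensome(table)
    m = len(table)
    table["rank"] = np.arange(1, m + 1)
    table["percentile"] = 100.0 * (m - table["rank"]) / m
    table["is_induced_ct"] = (table["cqv"] < q_max) & (table["gmfc_log2"] > lfc_min)
    table["is_repressed_ct"] = (table["cqv"] < q_max) & (table["gmfc_log2"] < -lfc_min)
    return table[CONSENSOME_COLUMNS]


def _sort_consensome(table: pd.DataFrame) -> pd.DataFrame:
    """CPV ascending, then |gmfc_log2| descending, then gene_id (stable)."""
    t = table.assign(_abs=table["gmfc_log2"].abs(), _neg=lambda d: -d["_abs"])
    t = t.sort_values(
        by=["cpv", "_neg", "gene_id"], kind="mergesort", ignore_index=True
    )
    return t.drop(columns=["_abs", "_neg"])


def designate_confidence_sets(
    consensome: pd.DataFrame,
    q_max: float = 0.05,
    lfc_min: float = 1.0,
) -> tuple[frozenset[str], frozenset[str]]:
    """Induced / repressed confidence transcript sets from a consensome table.

    induced = {CQV < q_max and gmfc_log2 > lfc_min}; repressed mirrors with
    gmfc_log2 < -lfc_min.  A gene can belong to at most one set.
    """
    induced = consensome.loc[
        (consensome["cqv"] < q_max) & (consensome["gmfc_log2"] > lfc_min), "gene_id"
    ]
    repressed = consensome.loc[
        (consensome["cqv"] < q_max) & (consensome["gmfc_log2"] < -lfc_min), "gene_id"
    ]
    return frozenset(induced), frozenset(repressed)


class ConsensomeModel:
    """Consensus-signature model over a compendium of DE contrasts.

    Parameters
    ----------
    compendium : list of ContrastTable
        The per-contrast gene-level differential-expression tables.
    alpha : float
        Per-contrast significance call threshold (strict inequality).
    p0 : float
        Null per-contrast success probability of the binomial model.

    Examples
    --------
    >>> model = ConsensomeModel(contrasts)           # doctest: +SKIP
    >>> res = model.fit()                            # doctest: +SKIP
    >>> res.table.head(); res.induced; res.summary() # doctest: +SKIP
    """

    def __init__(
        self,
        compendium: Iterable[ContrastTable],
        alpha: float = 0.05,
        p0: float = 0.05,
    ) -> None:
        self.compendium = list(compendium)
        if not self.compendium:
            raise InputError("empty compendium")
        self.alpha = alpha
        self.p0 = p0

    @classmethod
    def from_dataframes(
        cls, tables: dict[str, pd.DataFrame], **kwargs
    ) -> "ConsensomeModel":
        """Build from {contrast_id: DataFrame} with the contrast schema."""
        return cls(
            [ContrastTable(cid, df) for cid, df in tables.items()], **kwargs
        )

    def fit(self, q_max: float = 0.05, lfc_min: float = 1.0) -> "ConsensomeResults":
        table = build_consensome(
            self.compendium, alpha=self.alpha, p0=self.p0, q_max=q_max,
            lfc_min=lfc_min,
        )
        return ConsensomeResults(self, table, q_max=q_max, lfc_min=lfc_min)


class ConsensomeResults:
    """Fitted consensome: ranked table, confidence sets, and reports."""

    def __init__(
        self,
        model: ConsensomeModel,
        table: pd.DataFrame,
        q_max: float,
        lfc_min: float,
    ) -> None:
        self.model = model
        self.table = table
        self.q_max = q_max
        self.lfc_min = lfc_min
        self.induced, self.repressed = designate_confidence_sets(
            table, q_max=q_max, lfc_min=lfc_min
        )

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def gene_universe(self) -> frozenset[str]:
        return frozenset(self.table["gene_id"])

    def hct_set(self, pct: float = 95.0) -> frozenset[str]:
        """Genes in the top (100 - pct)% of the ranking (ceiling rule)."""
        from .screen import designate_hcts

        return designate_hcts(self.table, pct=pct)

    def display_percentile(self, gene_id: str) -> int:
        """Integer (floored) percentile for display, as in report tables."""
        row = self.table.loc[self.table["gene_id"] == gene_id]
        if row.empty:
            raise InputError(f"gene {gene_id!r} not in consensome")
        return int(math.floor(row["percentile"].iloc[0]))

    def summary(self) -> str:
        t = self.table
        lines = [
            "Consensome results",
            "==================",
            f"contrasts:             {len(self.model.compendium)}",
            f"genes retained:        {self.n_genes}",
            f"alpha / p0:            {self.model.alpha} / {self.model.p0}",
            f"CQV < {self.q_max}:            {int((t['cqv'] < self.q_max).sum())} genes",
            f"induced CTs (GMFC > {self.lfc_min}):   {len(self.induced)}",
            f"repressed CTs (GMFC < -{self.lfc_min}): {len(self.repressed)}",
            "",
            "top 10 genes (gene_id, k/n, cpv, cqv, gmfc_log2, %ile):",
        ]
        for _, r in t.head(10).iterrows():
            lines.append(
                f"  {r.gene_id:<12} {int(r.n_sig)}/{int(r.n_assayed)}  "
                f"{fmt_float(r.cpv):>10}  {fmt_float(r.cqv):>10}  "
                f"{r.gmfc_log2:+.3f}  {int(math.floor(r.percentile))}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from .io import write_consensome_tsv

        write_consensome_tsv(self.table, path)
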