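"""ChIP-Seq peak integration: percentilized peak strengths, the top-half
direct-target set, and concordance of knockout fold changes with consensome
fold changes over putatively bound genes.

Peaks arrive with a pre-supplied peak -> gene mapping (nearest-gene
assignment is upstream of this package).  Per-gene strength is the maximum
peak score over the gene's peaks; genes are then ranked and percentilized so
that a percentile cut (50th by default) yields the strongly-bound,
direct-target candidate set.
"""

from __future__ import annotations

from typing import Collection, Mapping

import numpy as np
import pandas as pd

from ._util import top_count
from .datatypes import KOGeneSets
from .errors import InputError
from .stats import CorrelationResult, OverlapResult, fc_correlation, hypergeom_overlap

__all__ = [
    "percentilize_peaks",
    "lz_threshold",
    "direct_target_enrichment",
    "fc_correlation",
    "correlate_fold_changes",
]

PEAK_COLUMNS = ["peak_id", "gene_id", "strength"]


def percentilize_peaks(peaks: pd.DataFrame, agg: str = "max") -> pd.DataFrame:
    """Per-gene peak-strength percentiles from a peak table.

    Parameters
    ----------
    peaks : pandas.DataFrame
        Columns ``peak_id, gene_id, strength``; a gene may carry multiple
        peaks.  Strengths must be non-negative.
    agg : {"max", "mean"}
        Per-gene aggregation over that gene's peaks.  The default keeps the
        best (strongest) peak per gene, which is stable to peak splitting.

    Returns
    -------
    pandas.DataFrame
        One row per distinct gene: ``gene_id, strength, rank, percentile``,
        ranked by strength descending (ties broken by gene id for
        determinism); percentile = 100 * (n - rank) / n over distinct genes.
    """
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise InputError(f"peak table missing columns {missing}")
    if len(peaks) == 0:
        raise InputError("empty peak table")
    if (peaks["strength"] < 0).any() or peaks["strength"].isna().any():
        raise InputError("peak strengths must be non-negative and finite")
    if agg not in ("max", "mean"):
        raise InputError(f"agg must be 'max' or 'mean', got {agg!r}")
    per_gene = (
        peaks.groupby("gene_id")["strength"].agg(agg).rename("strength").reset_index()
    )
    per_gene = per_gene.sort_values(
        by=["strength", "gene_id"], ascending=[False, True], kind="mergesort",
        ignore_index=True,
    )
    n = len(per_gene)
    per_gene["rank"] = np.arange(1, n + 1)
    per_gene["percentile"] = 100.0 * (n - per_gene["rank"]) / n
    return per_gene


def lz_threshold(gene_percentiles: pd.DataFrame, pct: float = 50.0) -> frozenset[str]:
    """Genes in the top ``pct``-th percentile band of peak strength.

    The top-half cut (pct=50) is the direct-target candidate set; the top
    ``ceil((100 - pct)% * n)`` ranked genes are returned.
    """
    n = len(gene_percentiles)
    if n == 0:
        raise InputError("empty gene percentile table")
    m = top_count(n, pct)
    ranked = gene_percentiles.sort_values("rank")
    return frozenset(ranked["gene_id"].iloc[:m])


def direct_target_enrichment(
    ko_sets: KOGeneSets,
    lz_set: Collection[str],
    induced_ct: Collection[str],
    repressed_ct: Collection[str],
    universe: Collection[str],
) -> dict[str, OverlapResult]:
    """Enrichment of bound, knockout-responsive genes in confidence sets.

    Tests (up & lz_set) against the induced confidence set and
    (down & lz_set) against the repressed confidence set, both within the
    supplied universe.  Returns ``{"induced": ..., "repressed": ...}``.
    """
    uni = frozenset(universe)
    lz = frozenset(lz_set) & uni
    return {
        "induced": hypergeom_overlap(ko_sets.up & lz, frozenset(induced_ct) & uni, uni),
        "repressed": hypergeom_overlap(
            ko_sets.down & lz, frozenset(repressed_ct) & uni, uni
        ),
    }


def correlate_fold_changes(
    ko_lfc: Mapping[str, float],
    consensome_lfc: Mapping[str, float],
    subset: Collection[str],
) -> CorrelationResult:
    """Pearson concordance of knockout vs consensome log2 fold changes.

    The subset (typically confidence-set genes within the bound top-half
    set) must have both values present for every gene; genes are paired in
    sorted order for determinism.
    """
    genes = sorted(subset)
    if len(genes) < 3:
        raise InputError(f"need at least 3 subset genes, got {len(genes)}")
    missing = [g for g in genes if g not in ko_lfc or g not in consensome_lfc]
    if missing:
        raise InputError(
            f"{len(missing)} subset genes lack paired fold changes "
            f"(first: {missing[0]!r})"
        )
    x = np.array([ko_lfc[g] for g in genes], dtype=float)
    y = np.array([consensome_lfc[g] for g in genes], dtype=float)
    return fc_correlation(x, y)
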