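"""High-confidence target (HCT) designation and the footprint intersection
screen.

A node's HCTs are the genes in the top percentile band (95th by default) of
its consensome.  The screen computes, for every node x knockout-direction
pair, the one-sided hypergeometric overlap between the node's HCT set and the
knockout-derived up/down gene set, then controls the FDR with
Benjamini-Hochberg separately within each modality x direction family.  A
significant, enriched intersection is read as a regulatory footprint: evidence
that the node's activity shaped the knockout response.

Second-order enrichment (:func:`node_set_enrichment`) applies the same
hypergeometric contract at the node level — e.g. phenotype-ontology term
members or curated interactor lists against the set of footprinted nodes.
"""

from __future__ import annotations

import math
from typing import Collection

import numpy as np
import pandas as pd

from ._util import top_count
from .datatypes import HCTLibrary, KOGeneSets, ContrastTable
from .errors import InputError
from .stats import OverlapResult, bh_adjust, hypergeom_overlap

__all__ = [
    "designate_hcts",
    "derive_ko_gene_sets",
    "hypergeom_overlap",
    "intersection_screen",
    "node_set_enrichment",
    "benchmark_confidence_set",
    "IntersectionScreen",
    "ScreenResults",
]

SCREEN_COLUMNS = [
    "node_id",
    "node_family",
    "modality",
    "direction",
    "k",
    "gene_set_size",
    "hct_size",
    "universe_size",
    "odds_ratio",
    "pvalue",
    "qvalue",
    "degenerate",
]


def designate_hcts(consensome: pd.DataFrame, pct: float = 95.0) -> frozenset[str]:
    """Genes in the ``pct``-th percentile of a ranked consensome.

    Takes the top ``ceil((100 - pct)% * n)`` ranked genes, so the cut is
    never empty for pct < 100 (a 12525-gene consensome yields 627 HCTs at
    pct=95).
    """
    n = len(consensome)
    if n == 0:
        raise InputError("empty consensome")
    m = top_count(n, pct)
    ranked = consensome.sort_values("rank")
    return frozenset(ranked["gene_id"].iloc[:m])


def derive_ko_gene_sets(
    ko: ContrastTable, fc_min: float = 1.5, p_max: float = 0.05
) -> KOGeneSets:
    """Knockout up/down gene sets with the |FC| > fc_min, p < p_max screen.

    ``fc_min`` is on the linear fold-change scale; the cut applies to
    |log2fc| > log2(fc_min).  Only assayed rows are considered.
    """
    if fc_min <= 1:
        raise InputError(f"fc_min must exceed 1 (linear scale), got {fc_min}")
    if not 0 < p_max <= 1:
        raise InputError(f"p_max must be in (0, 1], got {p_max}")
    d = ko.data.loc[ko.data["assayed"].astype(bool)]
    lcut = math.log2(fc_min)
    sig = d["pvalue"] < p_max
    up = frozenset(d.loc[sig & (d["log2fc"] > lcut), "gene_id"])
    down = frozenset(d.loc[sig & (d["log2fc"] < -lcut), "gene_id"])
    return KOGeneSets(up=up, down=down, fc_min=fc_min, p_max=p_max)


def intersection_screen(
    library: HCTLibrary,
    ko_sets: KOGeneSets,
    universe: Collection[str],
) -> pd.DataFrame:
    """Run the footprint intersection screen over an HCT library.

    One record per node x direction.  Gene sets and HCT sets are restricted
    to the supplied universe (the defensible default universe is the genes
    jointly observed in the knockout table and the library).  BH adjustment
    is applied separately within each modality x direction family.  Records
    are sorted by (direction, qvalue ascending, odds_ratio descending).
    """
    if len(library) == 0:
        raise InputError("empty HCT library")
    uni = frozenset(universe)
    if not uni:
        raise InputError("empty universe")
    sets = {"up": ko_sets.up & uni, "down": ko_sets.down & uni}

    rows = []
    for entry in library:
        hct = entry.hct_genes & uni
        for direction, gene_set in sets.items():
            if hct:
                res = hypergeom_overlap(gene_set, hct, uni)
            else:
                res = OverlapResult(0, len(gene_set), 0, len(uni), 1.0, 1.0, True)
            rows.append(
                {
                    "node_id": entry.node_id,
                    "node_family": entry.node_family,
                    "modality": entry.modality,
                    "direction": direction,
                    "k": res.k,
                    "gene_set_size": res.size_a,
                    "hct_size": res.size_b,
                    "universe_size": res.universe_size,
                    "odds_ratio": res.odds_ratio,
                    "pvalue": res.pvalue,
                    "degenerate": res.degenerate,
                }
            )
    table = pd.DataFrame(rows)
    table["qvalue"] = np.nan
    for (_, _), idx in table.groupby(["modality", "direction"]).groups.items():
        table.loc[idx, "qvalue"] = bh_adjust(table.loc[idx, "pvalue"].to_numpy())
    table = table.sort_values(
        by=["direction", "qvalue", "odds_ratio", "node_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
        ignore_index=True,
    )
    return table[SCREEN_COLUMNS]


def node_set_enrichment(
    hit_nodes: Collection[str],
    annotated_nodes: Collection[str],
    node_universe: Collection[str],
) -> OverlapResult:
    """Over-representation of annotated nodes among footprinted (hit) nodes.

    The same hypergeometric / odds-ratio contract as
    :func:`hypergeom_overlap`, applied at the node level relative to the
    declared node universe (e.g. all 691 nodes of a library).
    """
    return hypergeom_overlap(hit_nodes, annotated_nodes, node_universe)


def benchmark_confidence_set(
    confidence_set: Collection[str],
    reference_set: Collection[str],
    universe: Collection[str],
) -> OverlapResult:
    """Benchmark a confidence-transcript set against a reference gene set.

    Delegates to :func:`hypergeom_overlap`; used e.g. to validate an induced
    confidence set against a hallmark gene signature.
    """
    return hypergeom_overlap(confidence_set, reference_set, universe)


class IntersectionScreen:
    """Footprint screen model: an HCT library against knockout gene sets.

    Parameters
    ----------
    library : HCTLibrary
        Node -> HCT gene-set entries, each tagged with a modality.
    ko_sets : KOGeneSets
        Knockout-derived up/down gene sets.
    universe : collection of str, optional
        Gene universe for the hypergeometric tests.  Defaults to the genes
        jointly present in the library and in ``ko_universe`` when given,
        else the library's own gene universe.
    ko_universe : collection of str, optional
        All genes observed in the knockout experiment.
    """

    def __init__(
        self,
        library: HCTLibrary,
        ko_sets: KOGeneSets,
        universe: Collection[str] | None = None,
        ko_universe: Collection[str] | None = None,
    ) -> None:
        self.library = library
        self.ko_sets = ko_sets
        if universe is not None:
            self.universe = frozenset(universe)
        else:
            lib_uni = library.gene_universe() | ko_sets.up | ko_sets.down
            self.universe = (
                lib_uni & frozenset(ko_universe) if ko_universe is not None else lib_uni
            )
        if not self.universe:
            raise InputError("empty screen universe")

    def fit(self) -> "ScreenResults":
        table = intersection_screen(self.library, self.ko_sets, self.universe)
        return ScreenResults(self, table)


class ScreenResults:
    """Fitted intersection screen: per node x direction overlap records."""

    def __init__(self, model: IntersectionScreen, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        return self.table.loc[self.table["qvalue"] < q_max].reset_index(drop=True)

    def significant_nodes(
        self, direction: str, q_max: float = 0.05
    ) -> frozenset[str]:
        t = self.table
        return frozenset(
            t.loc[(t["direction"] == direction) & (t["qvalue"] < q_max), "node_id"]
        )

    def enrich(
        self,
        annotated_nodes: Collection[str],
        direction: str,
        q_max: float = 0.05,
        node_universe: Collection[str] | None = None,
    ) -> OverlapResult:
        """Node-level enrichment of an annotation among footprinted nodes."""
        uni = (
            frozenset(node_universe)
            if node_universe is not None
            else frozenset(self.model.library.node_ids())
        )
        return node_set_enrichment(
            self.significant_nodes(direction, q_max), annotated_nodes, uni
        )

    def summary(self) -> str:
        t = self.table
        lines = [
            "HCT intersection screen",
            "=======================",
            f"nodes:            {len(self.model.library)}",
            f"universe size:    {len(self.model.universe)}",
            f"KO up / down:     {len(self.model.ko_sets.up)} / "
            f"{len(self.model.ko_sets.down)}",
            f"records:          {len(t)}",
            f"Q < 0.05:         {int((t['qvalue'] < 0.05).sum())}",
            "",
            "top 10 footprints (node, modality, dir, k, OR, p, Q):",
        ]
        top = t.sort_values(["qvalue", "pvalue"]).head(10)
        for _, r in top.iterrows():
            lines.append(
                f"  {r.node_id:<14} {r.modality:<14} {r.direction:<4} "
                f"{int(r.k):>4}  {r.odds_ratio:8.2f}  {r.pvalue:9.3g}  "
                f"{r.qvalue:9.3g}"
            )
        return "\n".join(lines)

    def plot_footprint(self, direction: str = "down", ax=None):
        """Regulatory footprint scatter: -log10 Q vs odds ratio per node."""
        from .plots import footprint_scatter

        return footprint_scatter(self.table, direction=direction, ax=ax)
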