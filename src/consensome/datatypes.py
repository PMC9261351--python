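"""Core data containers shared across the pipeline.

A *contrast* is one differential-expression comparison (e.g. a time point vs
day 0) summarised per gene as a signed log2 fold change, a nominal p-value and
an assayed flag.  A *node* is a signaling pathway entity (receptor, enzyme,
transcription factor, co-node) with a set of high-confidence transcriptional
targets (HCTs).  Annotation maps carry term -> member sets for second-order
enrichment (phenotype ontology terms, interactor benchmarks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

CONTRAST_COLUMNS = ["gene_id", "log2fc", "pvalue", "assayed"]


@dataclass
class ContrastTable:
    """One differential-expression contrast.

    Parameters
    ----------
    contrast_id : str
        Identifier of the comparison.
    data : pandas.DataFrame
        Columns ``gene_id`` (str), ``log2fc`` (float), ``pvalue`` (float),
        ``assayed`` (bool).  For assayed rows, ``pvalue`` must lie in (0, 1]
        and ``log2fc`` must be finite.  Non-assayed rows carry NaN.
    """

    contrast_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CONTRAST_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(
                f"contrast {self.contrast_id!r}: missing columns {missing}"
            )
        if self.data["gene_id"].duplicated().any():
            dupes = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"]
            raise InputError(
                f"contrast {self.contrast_id!r}: duplicate gene_id "
                f"{dupes.iloc[0]!r}"
            )
        assayed = self.data["assayed"].astype(bool)
        p = self.data.loc[assayed, "pvalue"]
        if ((p <= 0) | (p > 1) | p.isna()).any():
            bad = self.data.loc[assayed].loc[(p <= 0) | (p > 1) | p.isna(), "gene_id"]
            raise InputError(
                f"contrast {self.contrast_id!r}: pvalue outside (0, 1] for "
                f"gene {bad.iloc[0]!r}"
            )
        lfc = self.data.loc[assayed, "log2fc"]
        if (~np.isfinite(lfc)).any():
            raise InputError(
                f"contrast {self.contrast_id!r}: non-finite log2fc in assayed rows"
            )

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene_id"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class HCTEntry:
    """One node's high-confidence transcriptional target set."""

    node_id: str
    node_family: str
    modality: str  # "transcriptomic" | "chipseq"
    hct_genes: frozenset[str]
    expression_percentile: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("transcriptomic", "chipseq"):
            raise InputError(
                f"node {self.node_id!r}: modality must be 'transcriptomic' or "
                f"'chipseq', got {self.modality!r}"
            )
        if not self.hct_genes:
            raise InputError(f"node {self.node_id!r}: empty HCT gene set")


@dataclass
class HCTLibrary:
    """A library of node -> HCT gene-set entries keyed by unique node id."""

    entries: dict[str, HCTEntry] = field(default_factory=dict)

    def add(self, entry: HCTEntry) -> None:
        if entry.node_id in self.entries:
            raise InputError(f"duplicate node_id {entry.node_id!r}")
        self.entries[entry.node_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __getitem__(self, node_id: str) -> HCTEntry:
        return self.entries[node_id]

    def node_ids(self) -> list[str]:
        return list(self.entries)

    def by_modality(self, modality: str) -> "HCTLibrary":
        return HCTLibrary(
            {k: v for k, v in self.entries.items() if v.modality == modality}
        )

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self:
            out |= e.hct_genes
        return frozenset(out)


@dataclass(frozen=True)
class KOGeneSets:
    """Up/down-regulated gene sets from a knockout contrast.

    Derived with the fold-change / p-value screen |FC| > fc_min (linear scale)
    and p < p_max; up and down are disjoint by construction.
    """

    up: frozenset[str]
    down: frozenset[str]
    fc_min: float = 1.5
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise InputError("up and down KO gene sets overlap")


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    label: str
    members: frozenset[str]


@dataclass
class AnnotationMap:
    """term_id -> member set (genes or nodes) with a display label per term."""

    terms: dict[str, AnnotationTerm] = field(default_factory=dict)

    def add(self, term: AnnotationTerm) -> None:
        if term.term_id in self.terms:
            raise InputError(f"duplicate term_id {term.term_id!r}")
        self.terms[term.term_id] = term

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> AnnotationTerm:
        return self.terms[term_id]


@dataclass
class SimTruth:
    """Ground truth planted by the synthetic-data generator."""

    planted_up: frozenset[str] = frozenset()
    planted_down: frozenset[str] = frozenset()
    active_nodes: frozenset[str] = frozenset()
    enriched_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise InputError("planted_up and planted_down overlap")
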