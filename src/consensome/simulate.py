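"""Synthetic-data generator with known planted structure.

Emulates the pipeline's inputs end-to-end: a compendium of
differential-expression contrasts (a mixture of null genes with uniform
p-values and planted, consistently-regulated responder genes), a knockout
DE table, an HCT gene-set library with planted "active" nodes whose target
sets are enriched in knockout-regulated genes, annotation term maps with
terms enriched among active nodes, and a ChIP-Seq-style peak table.

Detection is the controlled primitive: a planted gene is "detected" in a
contrast with probability ``detect_prob``, in which case its p-value is
Uniform(0, 0.05) — always nominally significant — so the per-contrast
success probability that the consensus statistic consumes is exact rather
than emerging from an effect-size/test model.  Null p-values are
Uniform(0, 1].  One master seed deterministically spawns independent named
substreams per component, so re-running a single generator reproduces its
output byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from ._util import component_rng
from .datatypes import (
    AnnotationMap,
    AnnotationTerm,
    ContrastTable,
    HCTEntry,
    HCTLibrary,
    SimTruth,
)
from .errors import ConfigurationError, InputError

__all__ = [
    "SimConfig",
    "simulate_compendium",
    "simulate_ko_table",
    "simulate_hct_library",
    "simulate_annotations",
    "simulate_peak_table",
]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the reference study geometry: a ~10,000-gene universe
    assayed across five adipogenesis-style contrasts, with 5% of genes
    planted as consistent responders detected in 90% of contrasts at a
    planted |log2 FC| of 2 (fold change 4) against a null log2-FC scale of
    0.5.
    """

    n_genes: int = 10_000
    n_contrasts: int = 5
    frac_true: float = 0.05
    detect_prob: float = 0.9
    effect_mu: float = 2.0
    effect_sd: float = 0.5
    null_sd: float = 0.5
    assay_rate: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigurationError(f"n_genes must be >= 10, got {self.n_genes}")
        if self.n_contrasts < 1:
            raise ConfigurationError(
                f"n_contrasts must be >= 1, got {self.n_contrasts}"
            )
        for name in ("frac_true", "detect_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.assay_rate <= 1:
            raise ConfigurationError(
                f"assay_rate must be in (0, 1], got {self.assay_rate}"
            )
        for name in ("effect_sd", "null_sd"):
            v = getattr(self, name)
            if not v >= 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if not math.isfinite(self.effect_mu):
            raise ConfigurationError("effect_mu must be finite")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def gene_universe(n_genes: int) -> list[str]:
    """The shared gene-id namespace g000001 ... g<n>."""
    return [f"g{i:06d}" for i in range(1, n_genes + 1)]


def _open_uniform(rng: np.random.Generator, size: int, high: float = 1.0) -> np.ndarray:
    """Uniform draws on (0, high] (p-values must never be exactly zero)."""
    return high * (1.0 - rng.random(size))


def simulate_compendium(cfg: SimConfig) -> tuple[list[ContrastTable], SimTruth]:
    """Simulate a compendium of DE contrasts with planted responders.

    Planted genes carry a fixed per-gene direction; in each contrast they
    are detected with probability ``detect_prob`` (p ~ Uniform(0, 0.05),
    log2 FC ~ Normal(+/- effect_mu, effect_sd)) and otherwise behave as
    null (p ~ Uniform(0, 1], log2 FC ~ Normal(0, null_sd)).  The assay mask
    is Bernoulli(assay_rate) i.i.d. per gene x contrast; non-assayed cells
    carry NaN.

    Returns the contrast list and the ground truth (planted up/down sets).
    """
    rng = component_rng(cfg.seed, "compendium")
    genes = np.array(gene_universe(cfg.n_genes))
    n_planted = int(round(cfg.frac_true * cfg.n_genes))
    planted = rng.choice(cfg.n_genes, size=n_planted, replace=False)
    n_up = n_planted // 2 + n_planted % 2
    up_idx = planted[:n_up]
    down_idx = planted[n_up:]
    sign = np.zeros(cfg.n_genes)
    sign[up_idx] = 1.0
    sign[down_idx] = -1.0
    is_planted = sign != 0.0

    tables = []
    for j in range(cfg.n_contrasts):
        assayed = rng.random(cfg.n_genes) < cfg.assay_rate
        pvals = _open_uniform(rng, cfg.n_genes)
        lfcs = rng.normal(0.0, cfg.null_sd, cfg.n_genes)
        detected = is_planted & (rng.random(cfg.n_genes) < cfg.detect_prob)
        pvals = np.where(
            detected, np.maximum(0.05 * rng.random(cfg.n_genes), _TINY), pvals
        )
        planted_lfc = rng.normal(sign * cfg.effect_mu, cfg.effect_sd)
        lfcs = np.where(detected, planted_lfc, lfcs)
        data = pd.DataFrame(
            {
                "gene_id": genes,
                "log2fc": np.where(assayed, lfcs, np.nan),
                "pvalue": np.where(assayed, pvals, np.nan),
                "assayed": assayed,
            }
        )
        tables.append(ContrastTable(f"contrast_{j + 1:02d}", data))

    truth = SimTruth(
        planted_up=frozenset(genes[up_idx]),
        planted_down=frozenset(genes[down_idx]),
    )
    return tables, truth


def simulate_ko_table(
    universe: list[str], truth: SimTruth, cfg: SimConfig
) -> ContrastTable:
    """Simulate a knockout-vs-control DE table over a gene universe.

    Planted-up genes get log2 FC ~ Normal(+effect_mu, effect_sd) and
    p ~ Uniform(0, 0.01); planted-down genes mirror; null genes are
    centered at zero with p ~ Uniform(0, 1].  All genes are assayed.
    """
    uni = pd.Index(universe)
    outside = (truth.planted_up | truth.planted_down) - set(uni)
    if outside:
        raise InputError(
            f"{len(outside)} planted genes outside the universe "
            f"(first: {sorted(outside)[0]!r})"
        )
    rng = component_rng(cfg.seed, "ko")
    n = len(uni)
    sign = np.zeros(n)
    sign[uni.isin(truth.planted_up)] = 1.0
    sign[uni.isin(truth.planted_down)] = -1.0
    is_planted = sign != 0.0

    pvals = _open_uniform(rng, n)
    lfcs = rng.normal(0.0, cfg.null_sd, n)
    planted_p = np.maximum(0.01 * rng.random(n), _TINY)
    planted_lfc = rng.normal(sign * cfg.effect_mu, cfg.effect_sd)
    data = pd.DataFrame(
        {
            "gene_id": np.asarray(uni),
            "log2fc": np.where(is_planted, planted_lfc, lfcs),
            "pvalue": np.where(is_planted, planted_p, pvals),
            "assayed": np.ones(n, dtype=bool),
        }
    )
    return ContrastTable("ko_vs_wt", data)


def simulate_hct_library(
    universe: list[str],
    truth: SimTruth,
    n_nodes: int = 691,
    hct_size: int = 300,
    active_overlap_frac: float = 0.3,
    n_active: int = 0,
    frac_chipseq: float = 0.3,
    seed: int = 0,
) -> HCTLibrary:
    """Simulate a node -> HCT gene-set library with planted active nodes.

    Inactive nodes sample ``hct_size`` genes uniformly from the universe.
    Active nodes (the first ``n_active`` of a random node ordering) draw
    ``active_overlap_frac`` of their set from the planted knockout-regulated
    genes — direction alternating per active node (up, down, up, ...) — and
    the remainder uniformly.  ``truth.active_nodes`` is filled in place.
    Nodes are grouped into families of four; the last ``frac_chipseq``
    share of nodes carries the chipseq modality.
    """
    if not 0 <= active_overlap_frac <= 1:
        raise InputError(
            f"active_overlap_frac must be in [0, 1], got {active_overlap_frac}"
        )
    uni = np.asarray(universe)
    if hct_size > len(uni) or hct_size < 1:
        raise InputError(
            f"hct_size must be in [1, {len(uni)}], got {hct_size}"
        )
    if n_active > n_nodes:
        raise InputError("n_active exceeds n_nodes")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    node_ids = [f"node{i:04d}" for i in range(1, n_nodes + 1)]
    active_ids = list(rng.permutation(node_ids)[:n_active])
    pools = {
        "up": np.asarray(sorted(truth.planted_up)),
        "down": np.asarray(sorted(truth.planted_down)),
    }
    n_chip = int(round(frac_chipseq * n_nodes))
    library = HCTLibrary()
    for i, node_id in enumerate(node_ids):
        if node_id in active_ids:
            direction = "up" if active_ids.index(node_id) % 2 == 0 else "down"
            pool = pools[direction]
            n_from_pool = min(int(round(active_overlap_frac * hct_size)), len(pool))
            chosen = set(rng.choice(pool, size=n_from_pool, replace=False))
            rest = np.array([g for g in uni if g not in chosen])
            chosen |= set(
                rng.choice(rest, size=hct_size - n_from_pool, replace=False)
            )
            genes = frozenset(chosen)
        else:
            genes = frozenset(rng.choice(uni, size=hct_size, replace=False))
        library.add(
            HCTEntry(
                node_id=node_id,
                node_family=f"fam{i // 4:04d}",
                modality="chipseq" if i >= n_nodes - n_chip else "transcriptomic",
                hct_genes=genes,
            )
        )
    truth.active_nodes = frozenset(active_ids)
    return library


def simulate_annotations(
    nodes: list[str],
    truth: SimTruth,
    n_terms: int = 100,
    term_size: int = 16,
    enrich_frac: float = 0.8,
    n_enriched: int = 1,
    seed: int = 0,
) -> AnnotationMap:
    """Simulate term -> node annotation maps with planted enriched terms.

    The first ``n_enriched`` terms draw ``enrich_frac`` of their members
    from ``truth.active_nodes`` (as many as the pool allows) and the rest
    uniformly; remaining terms sample uniformly from the node universe.
    ``truth.enriched_terms`` is filled in place.
    """
    node_arr = np.asarray(nodes)
    if term_size > len(node_arr) or term_size < 1:
        raise InputError(
            f"term_size must be in [1, {len(node_arr)}], got {term_size}"
        )
    if not 0 <= enrich_frac <= 1:
        raise InputError(f"enrich_frac must be in [0, 1], got {enrich_frac}")
    if n_enriched > n_terms:
        raise InputError("n_enriched exceeds n_terms")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    active = np.asarray(sorted(truth.active_nodes))
    amap = AnnotationMap()
    enriched_ids = []
    for t in range(1, n_terms + 1):
        term_id = f"term{t:04d}"
        if t <= n_enriched:
            n_from_active = min(int(round(enrich_frac * term_size)), len(active))
            chosen = set(rng.choice(active, size=n_from_active, replace=False))
            rest = np.array([x for x in node_arr if x not in chosen])
            chosen |= set(
                rng.choice(rest, size=term_size - n_from_active, replace=False)
            )
            enriched_ids.append(term_id)
            members = frozenset(chosen)
        else:
            members = frozenset(rng.choice(node_arr, size=term_size, replace=False))
        amap.add(AnnotationTerm(term_id, f"synthetic term {t}", members))
    truth.enriched_terms = frozenset(enriched_ids)
    return amap


def simulate_peak_table(
    universe: list[str],
    truth: SimTruth | None = None,
    n_peaks: int = 679,
    planted_frac: float = 0.0,
    planted_strength_boost: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a ChIP-Seq-style peak table with a peak -> gene mapping.

    Peak strengths are log-normal (MACS2-score-like); each peak maps to a
    gene sampled with replacement from the universe, so some genes carry
    multiple peaks.  When ``planted_frac`` > 0 and truth is given, that
    fraction of peaks is assigned to planted knockout-regulated genes and
    their strengths multiplied by ``planted_strength_boost``, emulating
    preferential binding at regulated targets.

    Returns a DataFrame with columns ``peak_id, gene_id, strength`` plus
    fabricated BED coordinates (``chrom, start, end``; carried, not
    interpreted).
    """
    if n_peaks < 1:
        raise InputError(f"n_peaks must be >= 1, got {n_peaks}")
    if not 0 <= planted_frac <= 1:
        raise InputError(f"planted_frac must be in [0, 1], got {planted_frac}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    uni = np.asarray(universe)
    gene_ids = rng.choice(uni, size=n_peaks, replace=True)
    strengths = rng.lognormal(mean=4.0, sigma=1.0, size=n_peaks)
    if planted_frac > 0 and truth is not None:
        pool = np.asarray(sorted(truth.planted_up | truth.planted_down))
        if len(pool):
            n_pl = int(round(planted_frac * n_peaks))
            idx = rng.choice(n_peaks, size=n_pl, replace=False)
            gene_ids[idx] = rng.choice(pool, size=n_pl, replace=True)
            strengths[idx] *= planted_strength_boost
    return pd.DataFrame(
        {
            "peak_id": [f"peak{i:05d}" for i in range(1, n_peaks + 1)],
            "gene_id": gene_ids,
            "strength": np.round(strengths, 4),
            "chrom": "chr1",
            "start": np.arange(n_peaks) * 1000,
            "end": np.arange(n_peaks) * 1000 + 500,
        }
    )
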