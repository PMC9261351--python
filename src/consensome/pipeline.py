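"""End-to-end orchestration: configuration, staged execution, reporting.

A run proceeds consensome -> knockout gene sets -> HCT intersection screen ->
annotation enrichment -> ChIP-Seq integration, reading inputs from files or
generating them with the synthetic module, and writes a reproducible output
tree: consensome TSV, confidence-set GMT, screen TSV, enrichment TSV,
optional figures, and a machine-readable summary JSON echoing every
threshold and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .chipseq import (
    correlate_fold_changes,
    direct_target_enrichment,
    lz_threshold,
    percentilize_peaks,
)
from .core import ConsensomeModel
from .datatypes import SimTruth
from .errors import ConfigurationError, ConsensomeError
from .screen import IntersectionScreen, derive_ko_gene_sets, node_set_enrichment
from .simulate import (
    SimConfig,
    gene_universe,
    simulate_annotations,
    simulate_compendium,
    simulate_hct_library,
    simulate_ko_table,
    simulate_peak_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_sim_inputs"]


@dataclass(frozen=True)
class SimSection:
    """Synthetic-input parameters beyond the compendium SimConfig."""

    n_nodes: int = 691
    hct_size: int = 300
    active_overlap_frac: float = 0.3
    n_active: int = 10
    frac_chipseq: float = 0.3
    n_terms: int = 100
    term_size: int = 16
    enrich_frac: float = 0.8
    n_enriched: int = 1
    n_peaks: int = 679
    planted_frac: float = 0.3
    planted_strength_boost: float = 2.0


@dataclass
class RunConfig:
    """Validated run configuration.

    Either the input paths (``compendium_dir``, ``ko_path``, ...) or a
    ``simulate`` section must be supplied; unknown keys are rejected.
    """

    outdir: Path = Path("consensome_run")
    seed: int = 0
    # input paths (optional when simulating)
    compendium_dir: Path | None = None
    ko_path: Path | None = None
    library_path: Path | None = None
    peaks_bed: Path | None = None
    peaks_map: Path | None = None
    annotations_path: Path | None = None
    # thresholds
    alpha: float = 0.05
    p0: float = 0.05
    q_max: float = 0.05
    lfc_min: float = 1.0
    fc_min: float = 1.5
    p_max: float = 0.05
    hct_pct: float = 95.0
    lz_pct: float = 50.0
    screen_q_sig: float = 0.05
    benchmark_q_cut: float = 1e-20
    figures: bool = False
    # synthetic generation
    sim: SimConfig | None = None
    sim_extra: SimSection = field(default_factory=SimSection)

    def __post_init__(self) -> None:
        for name in ("alpha", "p0", "q_max", "screen_q_sig"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.p_max <= 1:
            raise ConfigurationError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.fc_min <= 1:
            raise ConfigurationError(f"fc_min must exceed 1, got {self.fc_min}")
        if not 0 <= self.hct_pct < 100 or not 0 <= self.lz_pct < 100:
            raise ConfigurationError("hct_pct and lz_pct must be in [0, 100)")
        if self.lfc_min < 0:
            raise ConfigurationError(f"lfc_min must be >= 0, got {self.lfc_min}")
        if self.sim is None and self.compendium_dir is None:
            raise ConfigurationError(
                "either a simulate section or a compendium_dir is required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(doc, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, doc: dict, base_dir: Path | None = None) -> "RunConfig":
        doc = dict(doc)
        sim = None
        sim_extra = SimSection()
        if "simulate" in doc:
            sim_doc = dict(doc.pop("simulate") or {})
            extra_names = {f.name for f in fields(SimSection)}
            extra = {k: sim_doc.pop(k) for k in list(sim_doc) if k in extra_names}
            known = {f.name for f in fields(SimConfig)}
            unknown = set(sim_doc) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown simulate keys: {sorted(unknown)}"
                )
            sim = SimConfig(**sim_doc)
            sim_extra = SimSection(**extra)
        path_keys = {
            "outdir", "compendium_dir", "ko_path", "library_path", "peaks_bed",
            "peaks_map", "annotations_path",
        }
        known = {f.name for f in fields(cls)} - {"sim", "sim_extra"}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for k in path_keys & set(doc):
            if doc[k] is not None:
                p = Path(doc[k])
                if base_dir is not None and not p.is_absolute():
                    p = base_dir / p
                doc[k] = p
        return cls(sim=sim, sim_extra=sim_extra, **doc)

    def echo(self) -> dict:
        out = {
            "seed": self.seed,
            "alpha": self.alpha,
            "p0": self.p0,
            "q_max": self.q_max,
            "lfc_min": self.lfc_min,
            "fc_min": self.fc_min,
            "p_max": self.p_max,
            "hct_pct": self.hct_pct,
            "lz_pct": self.lz_pct,
            "screen_q_sig": self.screen_q_sig,
            "benchmark_q_cut": self.benchmark_q_cut,
        }
        if self.sim is not None:
            out["simulate"] = {
                **self.sim.to_dict(),
                **{f.name: getattr(self.sim_extra, f.name) for f in fields(SimSection)},
            }
        return out


def write_sim_inputs(cfg: RunConfig, outdir: str | Path) -> SimTruth:
    """Generate and write the full synthetic input bundle to a directory.

    Emits per-contrast TSVs, the knockout TSV, the HCT library GMT, the
    annotation GMT, peaks (BED5 + mapping TSV), the ground-truth sidecar,
    and a manifest echoing the generator configuration.
    """
    if cfg.sim is None:
        raise ConfigurationError("write_sim_inputs requires a simulate section")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim, extra = cfg.sim, cfg.sim_extra
    universe = gene_universe(sim.n_genes)

    compendium, truth = simulate_compendium(sim)
    for ct in compendium:
        cio.write_contrast_tsv(ct, outdir / f"{ct.contrast_id}.tsv")
    ko = simulate_ko_table(universe, truth, sim)
    cio.write_contrast_tsv(ko, outdir / "ko_vs_wt.tsv")
    library = simulate_hct_library(
        universe, truth,
        n_nodes=extra.n_nodes, hct_size=extra.hct_size,
        active_overlap_frac=extra.active_overlap_frac, n_active=extra.n_active,
        frac_chipseq=extra.frac_chipseq, seed=sim.seed,
    )
    cio.write_hct_gmt(library, outdir / "hct_library.gmt")
    amap = simulate_annotations(
        library.node_ids(), truth,
        n_terms=extra.n_terms, term_size=extra.term_size,
        enrich_frac=extra.enrich_frac, n_enriched=extra.n_enriched, seed=sim.seed,
    )
    cio.write_annotation_gmt(amap, outdir / "annotations.gmt")
    peaks = simulate_peak_table(
        universe, truth,
        n_peaks=extra.n_peaks, planted_frac=extra.planted_frac,
        planted_strength_boost=extra.planted_strength_boost, seed=sim.seed,
    )
    cio.write_peaks_bed(peaks, outdir / "peaks.bed", outdir / "peak_to_gene.tsv")
    cio.write_truth_tsv(truth, outdir / "truth.tsv")
    cio.write_manifest(outdir / "manifest.json", kind="sim_inputs", config=cfg.echo())
    return truth


def _load_inputs(cfg: RunConfig, workdir: Path):
    """Load inputs from files, simulating them first if configured."""
    if cfg.sim is not None:
        indir = workdir / "inputs"
        write_sim_inputs(cfg, indir)
        compendium_dir = indir
        ko_path = indir / "ko_vs_wt.tsv"
        library_path = indir / "hct_library.gmt"
        annotations_path = indir / "annotations.gmt"
        peaks_bed = indir / "peaks.bed"
        peaks_map = indir / "peak_to_gene.tsv"
    else:
        compendium_dir = cfg.compendium_dir
        ko_path, library_path = cfg.ko_path, cfg.library_path
        annotations_path = cfg.annotations_path
        peaks_bed, peaks_map = cfg.peaks_bed, cfg.peaks_map

    contrast_paths = sorted(
        p for p in Path(compendium_dir).glob("*.tsv")
        if p.name not in ("ko_vs_wt.tsv", "peak_to_gene.tsv", "truth.tsv")
    )
    if not contrast_paths:
        raise ConfigurationError(f"no contrast TSVs found in {compendium_dir}")
    compendium = [cio.read_contrast_tsv(p) for p in contrast_paths]
    ko = cio.read_contrast_tsv(ko_path) if ko_path else None
    library = cio.read_hct_gmt(library_path) if library_path else None
    annotations = (
        cio.read_annotation_gmt(annotations_path) if annotations_path else None
    )
    peaks = (
        cio.read_peaks_bed(peaks_bed, peaks_map) if peaks_bed and peaks_map else None
    )
    return compendium, ko, library, annotations, peaks


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    Stage errors propagate with the stage name; partial outputs are marked
    incomplete in the manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.echo(), "stages": {}}
    stage = "load_inputs"
    try:
        compendium, ko, library, annotations, peaks = _load_inputs(cfg, outdir)

        stage = "consensome"
        model = ConsensomeModel(compendium, alpha=cfg.alpha, p0=cfg.p0)
        res = model.fit(q_max=cfg.q_max, lfc_min=cfg.lfc_min)
        res.to_tsv(outdir / "consensome.tsv")
        cio.write_gmt(
            {
                "induced_confidence_transcripts": (
                    f"CQV<{cfg.q_max} gmfc_log2>{cfg.lfc_min}", res.induced,
                ),
                "repressed_confidence_transcripts": (
                    f"CQV<{cfg.q_max} gmfc_log2<-{cfg.lfc_min}", res.repressed,
                ),
            },
            outdir / "confidence_sets.gmt",
        )
        summary["stages"]["consensome"] = {
            "n_genes": res.n_genes,
            "n_induced_ct": len(res.induced),
            "n_repressed_ct": len(res.repressed),
        }

        ko_sets = None
        if ko is not None:
            stage = "ko_gene_sets"
            ko_sets = derive_ko_gene_sets(ko, fc_min=cfg.fc_min, p_max=cfg.p_max)
            cio.write_gmt(
                {
                    "ko_up": (f"FC>{cfg.fc_min} p<{cfg.p_max}", ko_sets.up),
                    "ko_down": (f"FC<1/{cfg.fc_min} p<{cfg.p_max}", ko_sets.down),
                },
                outdir / "ko_sets.gmt",
            )
            summary["stages"]["ko_gene_sets"] = {
                "n_up": len(ko_sets.up), "n_down": len(ko_sets.down),
            }

        screen_res = None
        if library is not None and ko_sets is not None:
            stage = "intersection_screen"
            ko_universe = frozenset(ko.data["gene_id"])
            screen = IntersectionScreen(library, ko_sets, ko_universe=ko_universe)
            screen_res = screen.fit()
            cio.write_screen_tsv(screen_res.table, outdir / "screen.tsv")
            summary["stages"]["intersection_screen"] = {
                "n_nodes": len(library),
                "n_records": len(screen_res.table),
                "n_q_sig": int(
                    (screen_res.table["qvalue"] < cfg.screen_q_sig).sum()
                ),
            }
            if cfg.figures:
                from .plots import save_figure

                save_figure(
                    screen_res.plot_footprint("down"), outdir / "footprint_down.svg"
                )
                save_figure(
                    screen_res.plot_footprint("up"), outdir / "footprint_up.svg"
                )

        if annotations is not None and screen_res is not None:
            stage = "annotation_enrichment"
            node_universe = frozenset(library.node_ids())
            rows = []
            for direction in ("up", "down"):
                hits = screen_res.significant_nodes(direction, cfg.screen_q_sig)
                for term in annotations:
                    r = node_set_enrichment(hits, term.members, node_universe)
                    rows.append(
                        {
                            "term_id": term.term_id,
                            "label": term.label,
                            "direction": direction,
                            "k": r.k,
                            "n_hits": r.size_a,
                            "n_annotated": r.size_b,
                            "odds_ratio": r.odds_ratio,
                            "pvalue": r.pvalue,
                            "degenerate": r.degenerate,
                        }
                    )
            enr = pd.DataFrame(rows)
            enr.to_csv(
                outdir / "annotation_enrichment.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            summary["stages"]["annotation_enrichment"] = {
                "n_terms": len(annotations),
                "n_p01": int((enr["pvalue"] < 0.01).sum()),
            }

        if peaks is not None and ko_sets is not None:
            stage = "chipseq_integration"
            pergene = percentilize_peaks(peaks)
            lz = lz_threshold(pergene, pct=cfg.lz_pct)
            uni = frozenset(ko.data["gene_id"]) & res.gene_universe()
            enrich = direct_target_enrichment(
                ko_sets, lz, res.induced, res.repressed, uni
            )
            ko_lfc = dict(zip(ko.data["gene_id"], ko.data["log2fc"]))
            cons_lfc = dict(zip(res.table["gene_id"], res.table["gmfc_log2"]))
            corr_subset = sorted((res.induced | res.repressed) & lz & uni)
            corr = (
                correlate_fold_changes(ko_lfc, cons_lfc, corr_subset)
                if len(corr_subset) >= 3
                else None
            )
            chip = {
                "n_peaks": len(peaks),
                "n_mapped_genes": len(pergene),
                "n_lz": len(lz),
                "induced": _overlap_dict(enrich["induced"]),
                "repressed": _overlap_dict(enrich["repressed"]),
            }
            if corr is not None:
                chip["fc_correlation"] = {
                    "r": corr.r, "r2": corr.r2, "adj_r2": corr.adj_r2,
                    "pvalue": corr.pvalue, "n": corr.n,
                }
                if cfg.figures:
                    from .plots import fc_scatter, save_figure

                    ax = fc_scatter(
                        [ko_lfc[g] for g in corr_subset],
                        [cons_lfc[g] for g in corr_subset],
                    )
                    save_figure(ax, outdir / "fc_scatter.svg")
            summary["stages"]["chipseq_integration"] = chip

        stage = "summary"
        cio.write_manifest(outdir / "summary.json", kind="run_summary", **summary)
        return summary
    except Exception as exc:
        try:
            cio.write_manifest(
                outdir / "summary.json", kind="run_summary", incomplete=True,
                failed_stage=stage, error=str(exc), **summary,
            )
        except Exception:  # pragma: no cover - reporting best effort
            pass
        if isinstance(exc, ConsensomeError):
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        raise ConsensomeError(f"stage {stage!r}: {exc}") from exc


def _overlap_dict(r) -> dict:
    return {
        "k": r.k, "size_a": r.size_a, "size_b": r.size_b,
        "universe": r.universe_size, "odds_ratio": r.odds_ratio,
        "pvalue": r.pvalue, "degenerate": r.degenerate,
    }
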