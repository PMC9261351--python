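"""Readers and writers for the pipeline's interchange formats.

Everything is plain text: TSV for differential-expression tables, the
consensome and screen outputs; GMT for gene/node sets and annotation maps
(the interchange format every gene-set consumer in this domain reads); BED5
plus a peak -> gene mapping TSV for ChIP-Seq peaks; JSON for manifests and
summaries.  UTF-8, Unix newlines, floats rendered with 6 significant digits.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import fmt_float
from .datatypes import (
    AnnotationMap,
    AnnotationTerm,
    ContrastTable,
    HCTEntry,
    HCTLibrary,
    SimTruth,
)
from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = 1

CONTRAST_HEADER = ["gene_id", "log2fc", "pvalue", "assayed"]


def read_contrast_tsv(path: str | Path) -> ContrastTable:
    """Read one DE contrast from TSV (gene_id, log2fc, pvalue, assayed).

    ``assayed`` is 0/1; non-assayed rows may carry NA numerics.  Rows with
    unparseable numerics are rejected with their line numbers; duplicate
    gene ids and p-values outside (0, 1] raise integrity errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CONTRAST_HEADER if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")

    def parse_col(col: str, allow_na: bool) -> np.ndarray:
        raw = df[col].to_numpy()
        out = np.empty(len(raw))
        bad_lines = []
        for i, v in enumerate(raw):
            if v in ("", "NA", "nan") and allow_na:
                out[i] = np.nan
                continue
            try:
                out[i] = float(v)
            except ValueError:
                bad_lines.append(i + 2)  # header is line 1
        if bad_lines:
            raise SchemaError(
                f"{path.name}: unparseable {col} at lines {bad_lines[:5]}"
            )
        return out

    log2fc = parse_col("log2fc", allow_na=True)
    pvalue = parse_col("pvalue", allow_na=True)
    assayed_raw = df["assayed"].to_numpy()
    if not np.isin(assayed_raw, ["0", "1"]).all():
        raise SchemaError(f"{path.name}: assayed must be 0/1")
    assayed = assayed_raw == "1"

    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if len(dupes):
        raise IntegrityError(f"{path.name}: duplicate gene_id {dupes.iloc[0]!r}")
    p_assayed = pvalue[assayed]
    if np.any(np.isnan(p_assayed) | (p_assayed <= 0) | (p_assayed > 1)):
        bad = df["gene_id"].to_numpy()[assayed][
            np.isnan(p_assayed) | (p_assayed <= 0) | (p_assayed > 1)
        ]
        raise IntegrityError(
            f"{path.name}: pvalue outside (0, 1] for gene {bad[0]!r}"
        )
    data = pd.DataFrame(
        {
            "gene_id": df["gene_id"].to_numpy(),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "assayed": assayed,
        }
    )
    return ContrastTable(path.stem, data)


def write_contrast_tsv(table: ContrastTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CONTRAST_HEADER) + "\n")
        for row in table.data.itertuples(index=False):
            lfc = "NA" if not np.isfinite(row.log2fc) else fmt_float(row.log2fc)
            p = "NA" if not np.isfinite(row.pvalue) else fmt_float(row.pvalue)
            fh.write(f"{row.gene_id}\t{lfc}\t{p}\t{int(bool(row.assayed))}\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into {name: (description, member set)}.

    Each line is name, description, then tab-separated members (so at least
    three fields).  Duplicate members within a set are deduplicated with a
    warning; malformed lines raise with their line number.
    """
    path = Path(path)
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    f"{path.name}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in out:
                raise IntegrityError(f"{path.name}: duplicate set name {name!r}")
            if len(set(members)) < len(members):
                logger.warning(
                    "%s: line %d: duplicate members in set %r deduplicated",
                    path.name, lineno, name,
                )
            out[name] = (desc, frozenset(members))
    return out


def write_gmt(
    sets: Mapping[str, tuple[str, frozenset[str]]], path: str | Path
) -> None:
    """Write {name: (description, members)} as GMT with sorted members."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for name in sets:
            desc, members = sets[name]
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_hct_gmt(library: HCTLibrary, path: str | Path) -> None:
    """Write an HCT library as GMT; family/modality ride in the description."""
    sets = {
        e.node_id: (f"family={e.node_family};modality={e.modality}", e.hct_genes)
        for e in library
    }
    write_gmt(sets, path)


def read_hct_gmt(path: str | Path) -> HCTLibrary:
    """Read an HCT library GMT written by :func:`write_hct_gmt`."""
    library = HCTLibrary()
    for name, (desc, members) in read_gmt(path).items():
        meta = dict(
            kv.split("=", 1) for kv in desc.split(";") if "=" in kv
        )
        library.add(
            HCTEntry(
                node_id=name,
                node_family=meta.get("family", "unknown"),
                modality=meta.get("modality", "transcriptomic"),
                hct_genes=members,
            )
        )
    return library


def write_annotation_gmt(amap: AnnotationMap, path: str | Path) -> None:
    write_gmt({t.term_id: (t.label, t.members) for t in amap}, path)


def read_annotation_gmt(path: str | Path) -> AnnotationMap:
    amap = AnnotationMap()
    for name, (desc, members) in read_gmt(path).items():
        amap.add(AnnotationTerm(name, desc, members))
    return amap


def write_consensome_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a consensome table with the fixed column order and 6-sig-digit
    floats; the display percentile is floored to an integer alongside the
    exact value."""
    from .core import CONSENSOME_COLUMNS

    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CONSENSOME_COLUMNS) + "\n")
        for row in table.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.gene_id,
                        str(int(row.n_sig)),
                        str(int(row.n_assayed)),
                        fmt_float(row.cpv),
                        fmt_float(row.cqv),
                        fmt_float(row.gmfc_log2),
                        str(int(row.rank)),
                        fmt_float(row.percentile),
                        str(int(bool(row.is_induced_ct))),
                        str(int(bool(row.is_repressed_ct))),
                    ]
                )
                + "\n"
            )


def read_consensome_tsv(path: str | Path) -> pd.DataFrame:
    from .core import CONSENSOME_COLUMNS

    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in CONSENSOME_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing columns {missing}")
    df["is_induced_ct"] = df["is_induced_ct"].astype(bool)
    df["is_repressed_ct"] = df["is_repressed_ct"].astype(bool)
    return df[CONSENSOME_COLUMNS]


def write_screen_tsv(table: pd.DataFrame, path: str | Path) -> None:
    from .screen import SCREEN_COLUMNS

    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SCREEN_COLUMNS) + "\n")
        for row in table.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.node_id,
                        row.node_family,
                        row.modality,
                        row.direction,
                        str(int(row.k)),
                        str(int(row.gene_set_size)),
                        str(int(row.hct_size)),
                        str(int(row.universe_size)),
                        fmt_float(row.odds_ratio),
                        fmt_float(row.pvalue),
                        fmt_float(row.qvalue),
                        str(int(bool(row.degenerate))),
                    ]
                )
                + "\n"
            )


def write_peaks_bed(
    peaks: pd.DataFrame, bed_path: str | Path, map_path: str | Path
) -> None:
    """Write peaks as 5-column BED (chrom, start, end, peak_id, score) plus a
    peak_id -> gene_id mapping TSV."""
    bed_path, map_path = Path(bed_path), Path(map_path)
    with bed_path.open("w", encoding="utf-8", newline="\n") as fh:
        for row in peaks.itertuples(index=False):
            chrom = getattr(row, "chrom", "chr1")
            start = int(getattr(row, "start", 0))
            end = int(getattr(row, "end", start + 1))
            fh.write(
                f"{chrom}\t{start}\t{end}\t{row.peak_id}\t{fmt_float(row.strength)}\n"
            )
    with map_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("peak_id\tgene_id\n")
        for row in peaks.itertuples(index=False):
            fh.write(f"{row.peak_id}\t{row.gene_id}\n")


def read_peaks_bed(bed_path: str | Path, map_path: str | Path) -> pd.DataFrame:
    """Read a BED5 peak file and its peak -> gene mapping into a peak table."""
    bed_path, map_path = Path(bed_path), Path(map_path)
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "peak_id", "strength"],
    )
    if bed["peak_id"].duplicated().any():
        dupe = bed.loc[bed["peak_id"].duplicated(), "peak_id"].iloc[0]
        raise IntegrityError(f"{bed_path.name}: duplicate peak_id {dupe!r}")
    mapping = pd.read_csv(map_path, sep="\t", dtype=str)
    if set(mapping.columns) != {"peak_id", "gene_id"}:
        raise SchemaError(f"{map_path.name}: expected columns peak_id, gene_id")
    merged = bed.merge(mapping, on="peak_id", how="inner", validate="1:1")
    if len(merged) < len(bed):
        raise IntegrityError(
            f"{map_path.name}: {len(bed) - len(merged)} peaks lack gene mappings"
        )
    return merged[["peak_id", "gene_id", "strength", "chrom", "start", "end"]]


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    """Write the planted ground truth as a two-column category/id sidecar."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("category\tid\n")
        for cat, ids in [
            ("planted_up", truth.planted_up),
            ("planted_down", truth.planted_down),
            ("active_node", truth.active_nodes),
            ("enriched_term", truth.enriched_terms),
        ]:
            for x in sorted(ids):
                fh.write(f"{cat}\t{x}\n")


def read_truth_tsv(path: str | Path) -> SimTruth:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    by_cat = {
        cat: frozenset(df.loc[df["category"] == cat, "id"])
        for cat in ("planted_up", "planted_down", "active_node", "enriched_term")
    }
    return SimTruth(
        planted_up=by_cat["planted_up"],
        planted_down=by_cat["planted_down"],
        active_nodes=by_cat["active_node"],
        enriched_terms=by_cat["enriched_term"],
    )


def write_manifest(path: str | Path, **payload) -> None:
    """Write a manifest/summary JSON (schema-versioned, no timestamps)."""
    doc = {"schema_version": MANIFEST_SCHEMA_VERSION, **payload}
    Path(path).write_text(
        json.dumps(doc, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _json_default(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
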