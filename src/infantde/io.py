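"""Readers and writers for the pipeline's file formats.

Matrix Market coordinate integer counts with TSV gene/sample sidecars,
GMT gene sets, BED 3+ interval annotations (0-based half-open), TSV
regulon edge and patient DE tables, and JSON network dumps. All tables
are UTF-8, tab-separated, with a header row and "." for missing values;
parse errors carry file and line numbers.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .de import PseudobulkMatrix
from .network import ANNOTATION_CLASSES, AnnotatedInterval, HiDECORENetwork, RegulonEdge

__all__ = [
    "ParseError",
    "read_counts", "write_counts",
    "read_gmt", "write_gmt",
    "read_bed", "write_bed",
    "read_regulons", "write_regulons",
    "read_patient_de",
    "read_tsv", "write_tsv",
    "write_network", "read_network",
]

NA_TOKEN = "."


class ParseError(ValueError):
    """A file failed to parse; message carries file and line context."""


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False,
                       float_precision="round_trip")


def write_tsv(frame: pd.DataFrame, path) -> None:
    # %.17g keeps float round-trips lossless
    frame.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.17g")


def read_counts(mtx_path, genes_path, samples_path) -> PseudobulkMatrix:
    """Load a pseudobulk matrix from Matrix Market + TSV sidecars."""
    mat = spio.mmread(str(mtx_path))
    counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if not np.issubdtype(counts.dtype, np.integer):
        if np.any(counts != np.round(counts)):
            raise ParseError(f"{mtx_path}: non-integer count values")
        counts = counts.astype(np.int64)
    genes = read_tsv(genes_path)
    if "gene" not in genes.columns:
        raise ParseError(f"{genes_path}: missing 'gene' column")
    dupes = genes["gene"][genes["gene"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"{genes_path}: duplicate gene ids {sorted(set(dupes))[:10]}")
    samples = read_tsv(samples_path)
    return PseudobulkMatrix(counts, genes["gene"].tolist(), samples)


def write_counts(matrix: PseudobulkMatrix, mtx_path, genes_path, samples_path) -> None:
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(matrix.counts), field="integer")
    write_tsv(pd.DataFrame({"gene": matrix.gene_ids}), genes_path)
    write_tsv(matrix.sample_meta, samples_path)


def read_gmt(path) -> dict:
    """GMT: one set per line, 'name <tab> description <tab> gene...'."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{NA_TOKEN}\t{genes}\n")


def read_bed(path) -> list:
    """BED 3+ with annotation class in column 4 (0-based half-open)."""
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: need >= 4 BED columns")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            cls = name.split("|")[0]
            if cls not in ANNOTATION_CLASSES:
                raise ParseError(
                    f"{path}:{lineno}: unknown annotation class {cls!r} "
                    f"(expected one of {ANNOTATION_CLASSES})"
                )
            source = name.split("|", 1)[1] if "|" in name else ""
            intervals.append(AnnotatedInterval(chrom, start, end, cls, source))
    return intervals


def write_bed(intervals, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            name = iv.annotation_class + (f"|{iv.source}" if iv.source else "")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


REGULON_COLUMNS = ["tf", "region", "target", "tf2g_score", "r2g_score",
                   "role", "cell_context"]


def read_regulons(path) -> list:
    df = read_tsv(path)
    missing = set(REGULON_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing regulon columns {sorted(missing)}")
    edges = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        try:
            edges.append(
                RegulonEdge(tf=row.tf, region=row.region, target=row.target,
                            tf2g_score=float(row.tf2g_score),
                            r2g_score=float(row.r2g_score),
                            role=row.role, cell_context=row.cell_context)
            )
        except (TypeError, ValueError) as err:
            raise ParseError(f"{path}:{lineno}: {err}") from None
    return edges


def write_regulons(edges, path) -> None:
    write_tsv(
        pd.DataFrame(
            [{c: getattr(e, c) for c in REGULON_COLUMNS} for e in edges],
            columns=REGULON_COLUMNS,
        ),
        path,
    )


def read_patient_de(path, fdr_threshold: float = 1.0) -> pd.DataFrame:
    """Patient DE table; validation lives in disease.load_patient_de."""
    from .disease import load_patient_de

    return load_patient_de(read_tsv(path), fdr_threshold=fdr_threshold)


def write_network(network: HiDECORENetwork, path) -> None:
    """JSON dump of a lineage core network, stable key order."""
    payload = {
        "lineage": network.lineage,
        "nodes": [
            {"gene": n,
             "kind": "+".join(sorted(network.graph.nodes[n].get("kind", []))),
             "disease": network.node_disease.get(n, "none")}
            for n in sorted(network.graph.nodes)
        ],
        "edges": [
            {"tf": e.tf, "target": e.target, "region": e.region,
             "tf2g_score": e.tf2g_score, "r2g_score": e.r2g_score,
             "annotation_classes": sorted(network.edge_annotations.get(i, ()))}
            for i, e in enumerate(network.edges)
        ],
        "provenance": network.provenance,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_network(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
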