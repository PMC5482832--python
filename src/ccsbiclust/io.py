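"""Readers and writers: expression matrices (TSV/GCT) and bicluster JSON.

Matrices travel as tab-separated text with gene ids in the first column and
sample ids in the header, or as GCT 1.2.  Bicluster sets travel as a JSON
document that stores gene and sample *identifiers* (never positional
indices), so a document remains valid if the matrix rows are reordered.
All writers are deterministic: identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Bicluster, BiclusterSet, ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_biclusters",
    "write_biclusters",
    "read_symbol_map",
    "MatrixParseError",
    "SchemaVersionError",
]

FORMAT_VERSION = "1.0"


class MatrixParseError(ValueError):
    """Malformed expression-matrix file (duplicates, missing, non-numeric)."""


class SchemaVersionError(ValueError):
    """Bicluster document written by an incompatible format version."""


def _validate_frame(df: pd.DataFrame, path) -> ExpressionMatrix:
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    dup_genes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()].unique()
    if len(dup_genes):
        raise MatrixParseError(
            f"{path}: duplicate gene id(s): {', '.join(map(str, dup_genes[:5]))}"
        )
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise MatrixParseError(
            f"{path}: missing or non-numeric value at gene {gene_ids[r]!r}, "
            f"sample {sample_ids[c]!r} ({bad.shape[0]} bad cell(s) total)"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values)


def _check_header(path: Path, skip: int = 0) -> None:
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    dups: list[str] = []
    for s in samples:
        if s in seen:
            dups.append(s)
        seen.add(s)
    if dups:
        raise MatrixParseError(f"{path}: duplicate sample id(s): {', '.join(dups[:5])}")


def read_matrix(path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT.

    ``format`` is ``"tsv"``, ``"gct"``, or None to infer from the suffix.
    Duplicate identifiers and missing/non-numeric cells are hard errors with
    row/column diagnostics.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        _check_header(path)
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return _validate_frame(df, path)
    if format == "gct":
        with open(path) as fh:
            magic = fh.readline().strip()
        if not magic.startswith("#1."):
            raise MatrixParseError(f"{path}: not a GCT file (missing #1.x line)")
        _check_header(path, skip=2)
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0,
                         float_precision="round_trip")
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        return _validate_frame(df, path)
    raise ValueError(f"unknown matrix format {format!r}")


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write as TSV with full float precision (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_biclusters(bicluster_set: BiclusterSet, path) -> None:
    """Serialize a bicluster set as a stable-keyed JSON document."""
    doc = {
        "format_version": FORMAT_VERSION,
        "theta_used": bicluster_set.theta_used,
        "source": bicluster_set.source,
        "biclusters": [
            {
                "genes": list(bc.genes),
                "samples": list(bc.samples),
                "bscore": bc.bscore,
                "base_gene": bc.base_gene,
                "pattern_class": bc.pattern_class,
            }
            for bc in bicluster_set
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_biclusters(path) -> BiclusterSet:
    with open(path) as fh:
        doc = json.load(fh)
    version = str(doc.get("format_version", ""))
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise SchemaVersionError(
            f"{path}: format_version {version!r} not supported "
            f"(expected {FORMAT_VERSION})"
        )
    biclusters = [
        Bicluster(
            genes=tuple(rec["genes"]),
            samples=tuple(rec["samples"]),
            bscore=float(rec["bscore"]),
            base_gene=rec.get("base_gene"),
            pattern_class=rec.get("pattern_class", "merged"),
        )
        for rec in doc["biclusters"]
    ]
    return BiclusterSet(
        biclusters=biclusters,
        theta_used=float(doc["theta_used"]),
        source=doc.get("source", ""),
    )


def read_symbol_map(path) -> dict[str, str]:
    """Two-column TSV (probe id, gene symbol) → dict; header optional."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MatrixParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            if lineno == 1 and parts[0].lower() in {"probe", "probe_id", "gene_id", "id"}:
                continue
            out[parts[0]] = parts[1]
    return out
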