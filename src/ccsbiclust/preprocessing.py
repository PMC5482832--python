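"""Variance filtering and duplicate-probe collapsing for real expression data.

Microarray matrices carry many near-constant rows (housekeeping genes,
unexpressed probes) and multiple probe sets per gene symbol.  The standard
preparation for a correlation-based bicluster search removes rows whose
standard deviation falls below a cutoff (conventionally 2.0 on log-intensity
data) and keeps, per gene symbol, only the most variable probe set.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np

from .core import ExpressionMatrix

__all__ = ["filter_low_variance", "collapse_duplicates"]


def filter_low_variance(matrix: ExpressionMatrix, min_std: float) -> ExpressionMatrix:
    """Drop rows with standard deviation strictly below ``min_std``.

    Rows exactly at the cutoff are kept (the removal criterion is strict).
    Row order of the survivors is preserved.  An empty result is allowed but
    warned about.
    """
    if min_std < 0:
        raise ValueError("min_std must be >= 0")
    keep = np.flatnonzero(matrix.gene_stds >= min_std)
    if keep.size == 0:
        warnings.warn(
            f"variance filter at min_std={min_std} removed every row",
            stacklevel=2,
        )
    return matrix.subset_genes(keep.tolist())


def collapse_duplicates(
    matrix: ExpressionMatrix, gene_symbol_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Keep, per gene symbol, only the row with the highest standard deviation.

    ``gene_symbol_map`` maps every row id (probe set) to a symbol; rows
    sharing a symbol are duplicates.  Ties go to the first occurrence.
    Surviving rows keep their original ids, values and relative order, which
    makes the operation idempotent.
    """
    missing = [g for g in matrix.gene_ids if g not in gene_symbol_map]
    if missing:
        raise KeyError(
            f"symbol map missing {len(missing)} gene ids (first: {missing[0]!r})"
        )
    best: dict[str, int] = {}
    for i, gene in enumerate(matrix.gene_ids):
        sym = gene_symbol_map[gene]
        if sym not in best or matrix.gene_stds[i] > matrix.gene_stds[best[sym]]:
            best[sym] = i
    keep = sorted(best.values())
    return matrix.subset_genes(keep)
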