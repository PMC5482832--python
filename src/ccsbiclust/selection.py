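"""Similarity-pattern classes and sample-selection rules for a gene pair.

For a pair of genes, each sample is assigned to one of three candidate
sample sets by comparing both genes' values against their all-sample means:

* ``J1`` — up-regulated positive correlation: both genes strictly above
  their means;
* ``J2`` — down-regulated positive correlation: both strictly below;
* ``J3`` — negative correlation: the two deviations have strictly opposite
  signs.

All three inequalities are strict, so a sample where either gene sits
exactly at its mean belongs to no class (ties are measure-zero on real
expression data).  The means are over ALL samples of each gene, not over any
subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SampleMask

__all__ = ["SampleSplit", "split_samples"]


@dataclass(frozen=True)
class SampleSplit:
    """The three pairwise-disjoint candidate sample sets for a gene pair."""

    j1: SampleMask
    j2: SampleMask
    j3: SampleMask

    def masks(self) -> tuple[SampleMask, SampleMask, SampleMask]:
        return (self.j1, self.j2, self.j3)


def split_samples(
    x_i: np.ndarray,
    x_j: np.ndarray,
    mean_i: float,
    mean_j: float,
) -> SampleSplit:
    """Assign each sample to J1, J2, J3 or none for the gene pair (i, j).

    Parameters
    ----------
    x_i, x_j
        Full-length expression vectors of the two genes.
    mean_i, mean_j
        The genes' arithmetic means over all samples.
    """
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    di = x_i - mean_i
    dj = x_j - mean_j
    return SampleSplit(
        j1=SampleMask((di > 0) & (dj > 0)),
        j2=SampleMask((di < 0) & (dj < 0)),
        j3=SampleMask(di * dj < 0),
    )
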