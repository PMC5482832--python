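"""Prepare a probe-level expression matrix for the bicluster search.

Removes rows whose standard deviation falls below 2.0 (near-constant genes
cannot carry condition-specific correlation signal) and collapses probe sets
mapping to the same gene symbol, keeping the most variable probe per symbol.
"""

import numpy as np

from ccsbiclust.core import ExpressionMatrix
from ccsbiclust.preprocessing import collapse_duplicates, filter_low_variance

rng = np.random.default_rng(7)
n, m = 50, 12
values = rng.normal(size=(n, m)) * rng.uniform(0.5, 4.0, size=(n, 1))
probes = [f"probe_{i:03d}" for i in range(n)]
matrix = ExpressionMatrix(probes, [f"s{j}" for j in range(m)], values)
# several probes per gene symbol, as on a typical microarray
symbol_map = {p: f"GENE{int(i // 2):03d}" for i, p in enumerate(probes)}

filtered = filter_low_variance(matrix, min_std=2.0)
print(f"variance filter (std >= 2.0): {matrix.n_genes} -> "
      f"{filtered.n_genes} rows")
collapsed = collapse_duplicates(filtered, symbol_map)
print(f"duplicate collapse (best probe per symbol): {filtered.n_genes} -> "
      f"{collapsed.n_genes} rows")
stds = [float(np.std(collapsed.row(g))) for g in collapsed.gene_ids]
print(f"remaining row std range: {min(stds):.2f} .. {max(stds):.2f}")
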