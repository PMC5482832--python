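"""Show that biclusters are condition-dependent coexpression network modules.

A pre-merge CCS bicluster is a complete subgraph (edge density 1) of the
coexpression network built over its own samples — every gene pair is
correlated above theta there — while over other sample subsets the same gene
set is only sparsely connected.  The density table below makes that contrast
explicit; neighboring genes are non-members correlated with at least one
member over the bicluster's samples.
"""

from ccsbiclust import SearchConfig, find_bicluster_for_base, sort_by_variability
from ccsbiclust.network import module_report, neighboring_genes
from ccsbiclust.synthetic import generate_shift_scale

ds = generate_shift_scale(60, 40, 2, noise_sd=0.05, seed=4)
sm = sort_by_variability(ds.matrix)
cfg = SearchConfig(theta=0.8, adaptive_theta=False)

# two gene-disjoint biclusters, i.e. modules of two different conditions
biclusters = []
for i in range(sm.n_genes):
    bc = find_bicluster_for_base(sm, i, cfg)
    if bc is None:
        continue
    if all(not (set(bc.genes) & set(other.genes)) for other in biclusters):
        biclusters.append(bc)
    if len(biclusters) == 2:
        break

conditions = [bc.sample_mask(sm) for bc in biclusters]
report = module_report(sm, biclusters, conditions, theta=0.8)
print("edge density of each bicluster's gene set under each condition:")
for row in report:
    own = "own samples" if row.bicluster_index == row.condition_index else \
          f"samples of bicluster {row.condition_index}"
    print(f"  bicluster {row.bicluster_index} over {own}: "
          f"density {row.density:.3f} ({row.n_edges} edges, "
          f"{row.n_genes} genes)")

for k, bc in enumerate(biclusters):
    nb = neighboring_genes(sm, bc, conditions[k], theta=0.8)
    print(f"bicluster {k}: {len(nb)} neighboring gene(s) over its own samples")
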