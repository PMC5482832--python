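# Methods

## Model

A dataset is a real matrix D of n genes × m samples.  A bicluster C = (I, J)
is a gene subset I and a sample subset J such that every gene pair in I has
|r| > θ over J, where r is the Pearson coefficient computed over the samples
of J only (means and variances over J, not over all samples).  Condition
specificity is quantified by

    BScore(I, J) = |N ∩ M| / |N ∪ M|

with N the gene pairs from I correlated above θ over J and M the pairs
correlated above θ over the complement of J.  BScore = 0 means the
coexpression exists only inside J; the search keeps candidates with
BScore < 0.01.  The gene universe of N and M is the candidate's own gene set
I — the only set available at scoring time.

### Search

1. Rows are sorted by standard deviation (population convention, descending,
   stable).  The top `base_number` rows seed searches; by default all rows
   when n ≤ 2,000, else 1,000 (a cap that bounds the O(n³) worst case on
   large datasets).
2. For base g_i and each partner g_j after it in sorted order, each sample
   is assigned by strict sign comparison with the two genes' all-sample
   means to one of three candidate sample sets: J1 (both above), J2 (both
   below), J3 (opposite sides).  A sample exactly at a mean joins none; ties
   are measure-zero on real data.
3. For each candidate set with at least `min_samples` samples whose seed
   correlation satisfies |r| > θ, the gene set is grown greedily over all
   genes in sorted order: a gene joins iff its absolute masked correlation
   with every current member exceeds θ.  The sample set is frozen at seed
   time.
4. Candidates below the BScore bound compete per base gene: smallest BScore
   wins; ties go to the larger gene set, then to the earlier candidate in
   (partner, class) order.  The incumbent starts at +∞, so the first
   qualifying candidate is always accepted.
5. Merge: one pass over the per-base biclusters in sorted-base order; for
   each live ordered pair with intersecting gene sets, if the union of genes
   over the union of samples still scores BScore < 0.01 the first absorbs
   the second, in place, and the union participates in the remaining
   comparisons.  Surviving biclusters get their BScore recomputed on their
   final sets.  No fixed-point iteration beyond the nested loops; merged
   biclusters satisfy the BScore bound but not necessarily the all-pairs
   correlation property.
6. Adaptive θ: when enabled and a pass returns nothing, θ drops by 0.05 and
   the pass repeats until something is found or θ would reach 0.

The search is a pure function of (matrix, config).  Per-base searches are
independent, and results are assembled in sorted-base order before merging,
so any parallel execution order yields byte-identical output; with the
vectorized inner loops (per-mask standardized rows, correlation as dot
products) a thread pool adds nothing on typical problem sizes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| theta | 0.8 | minimum absolute pairwise correlation; 0.8 is the conventional level above which coexpression is strongly predictive of co-regulation |
| base_number | all (n ≤ 2000) / 1000 | number of most-variable genes used as search seeds |
| min_samples | 3 | smallest usable sample set; Pearson needs ≥ 3 points |
| min_genes | 3 | smallest reportable bicluster (see below) |
| bscore_threshold | 0.01 | condition-specificity bound |
| theta_step | 0.05 | adaptive-θ decrement |

**min_genes.** A bare seed pair always scores BScore 0 or 1: N is the single
pair, and M is empty or that same pair.  Nothing corroborates condition
specificity at two genes, and the sample-selection rules inflate pair
correlations by construction — conditioning on opposite-side deviations
(J3) induces |r| ≈ 2/π ≈ 0.64 between *independent* genes, so with tens of
background columns some pure-noise pairs clear θ = 0.8 by sampling noise
alone.  Requiring at least one successful augmentation (min_genes = 3)
suppresses these artifacts; min_genes = 2 restores the strictly literal
procedure.

**min_samples.** At the minimum of 3, any two 3-point vectors are weakly
constrained (|r| > 0.8 holds for roughly a quarter of random pairs), so
3-sample masks admit sizable artifact biclusters on pure noise even at
θ = 0.99.  The floor of 3 is kept as the permissive default; on real data a
larger value (5–10) is advisable and configurable.

## Synthetic benchmarks

The generator emulates the standard planted-bicluster designs:

* **constant**: background N(0, 1), k disjoint blocks of value 5 plus cell
  noise N(0, 0.1²);
* **shift-scale**: each block row is scale·base + shift of a shared
  N(0,1) base row, scale ∈ [0.5, 2] with a 20% sign flip (planting negative
  correlation), shift ∈ [−2, 2], plus cell noise.

Blocks are pairwise row- and column-disjoint, scattered (not contiguous),
sized ≈ n/(k+2) × m/(k+1) with ±20% jitter; five named presets cover the
benchmark grid from 100×75 with 3 blocks to 250×120 with 7.  Generation is a
pure function of its parameters including the seed.

What the generator does **not** emulate: sample-level covariance (batch or
condition effects shared across genes), heavy-tailed expression noise,
overlapping modules, and gene-specific variance profiles.  On real data the
complement set M is rarely empty — background correlation exists everywhere —
so the BScore gate is far more selective than on these benchmarks, where the
background is independent noise and M is almost always empty.

### Known behaviour on these benchmarks

Scores against planted truth (recovery/relevance with cell-level Jaccard
matching, the default; a gene-set-only mode is available) are structurally
limited for this procedure on iid-background data, for reasons worth knowing
before interpreting numbers:

1. *Cross-block modules.*  Two same-sign constant blocks form a genuine
   condition-dependent correlation submatrix (one block's genes are high
   exactly where the other's are background), which the negative-correlation
   class finds and the size tie-break prefers.  These bridge otherwise
   disjoint blocks during merging, and because the merge gate (BScore of the
   union) is trivially passed on a noise background, merging chains planted
   blocks into broad modules.  Recovery against single-block truth is
   correspondingly low (~0.15–0.25) even though the pre-merge per-block
   detections are nearly exact (cell-Jaccard ≈ 0.95).
2. *Mask dilution.*  Rule-derived sample sets include sign-matching
   background columns (~1/4 of background columns for the positive classes,
   ~1/2 for the negative class), so even a perfectly detected block carries
   extra samples, capping cell-level Jaccard well below 1 for shift-scale
   blocks.

These are properties of the published procedure on this class of synthetic
data, not tuning artifacts; the package implements the procedure as
specified and reports the scores it actually obtains.

## Evaluation

bicluster_similarity is the Jaccard index of cell sets ({(g, s): g ∈ I,
s ∈ J}); since a bicluster's cells form a product set, the intersection is
|I∩I′|·|J∩J′|.  Recovery = mean over expected biclusters of the best match
among found; relevance = the converse, computed after dropping exact
duplicates from the found set (rediscovering the same bicluster from many
base genes must not reweight the mean).  Both are 0 for an empty found set.

## Numerical choices

* Standard deviation uses the population convention (divide by count)
  throughout; sorting order is unaffected by the choice.
* Correlations are computed as dot products of rows standardized over the
  masked samples; a row constant over the mask standardizes to NaN and any
  comparison involving it counts as "not correlated" inside the search,
  while the public `masked_pearson` raises a degenerate-variance error.
* Computed correlations are clipped to [−1, 1] to absorb round-off.
* Zero-variance genes are excluded from seeding and growth.
* The adaptive-θ sequence is rounded to avoid floating-point drift
  (0.8, 0.75, 0.70, …).
* BScore returns 0 when both N and M are empty (only reachable through
  direct API calls; the search always has a correlated seed pair in N), and
  a complement smaller than min_samples yields an empty M, keeping BScore
  defined for biclusters spanning nearly all samples.
* The network module uses a closed edge threshold (|r| ≥ θ), the convention
  for coexpression-network displays, while the search uses strict > θ; the
  two are configured independently.

## Limitations

* The merge pass is the literal single-pass nested loop, not a transitive
  closure; output can depend on the per-base ordering of its input, which is
  fixed (sorted-base order) for determinism.
* On data whose background is truly independent noise, the BScore gate is
  permissive (M is empty almost everywhere) and merging is aggressive; see
  the benchmark notes above.
* Probe-to-symbol collapsing keeps the most variable probe; no averaging
  mode is provided.
* Expression values must be complete; missing values are a load-time error,
  and imputation is out of scope.
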