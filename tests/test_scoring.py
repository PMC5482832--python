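import numpy as np
import pytest

from ccsbiclust.core import SampleMask
from ccsbiclust.scoring import bscore, correlated_pairs
from .conftest import make_matrix
from .oracle import bscore_oracle, correlated_pairs_oracle


def affine_copies(base, coeffs, rng=None, pad=0):
    rows = [a * base + c for a, c in coeffs]
    if pad:
        rows = [np.concatenate([r, rng.normal(size=pad)]) for r in rows]
    return np.vstack(rows)


class TestCorrelatedPairs:
    def test_affine_copies_all_pairs(self, rng):
        base = rng.normal(size=6)
        m = make_matrix(affine_copies(base, [(1, 0), (2, 1), (-1.5, 3)]))
        res = correlated_pairs(m, m.gene_ids, SampleMask.full(6), theta=0.8)
        assert len(res.pairs) == 3

    def test_mask_below_min_samples_is_empty(self, rng):
        m = make_matrix(rng.normal(size=(4, 6)))
        res = correlated_pairs(m, m.gene_ids, SampleMask((1, 1, 0, 0, 0, 0)), 0.8)
        assert len(res.pairs) == 0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            m = make_matrix(rng.normal(size=(6, 10)))
            idx = sorted(rng.choice(10, size=6, replace=False).tolist())
            mask = SampleMask.from_indices(idx, 10)
            got = correlated_pairs(m, m.gene_ids, mask, 0.8).pairs
            got_idx = {tuple(sorted(m.gene_index(g) for g in p)) for p in got}
            assert got_idx == correlated_pairs_oracle(m.values, range(6), idx, 0.8)


class TestBScore:
    def test_inside_only_correlation_scores_zero(self, rng):
        # 3 affine copies over the first 5 columns, independent noise after
        base = rng.normal(scale=3, size=5)
        m = make_matrix(affine_copies(base, [(1, 0), (2, 1), (1.5, -2)],
                                      rng=rng, pad=6))
        mask = SampleMask.from_indices(range(5), 11)
        assert bscore(m, m.gene_ids, mask, 0.8) == 0.0

    def test_everywhere_correlation_scores_one(self, rng):
        base = rng.normal(scale=3, size=12)
        m = make_matrix(affine_copies(base, [(1, 0), (2, 1), (0.5, 3)]))
        mask = SampleMask.from_indices(range(6), 12)
        assert bscore(m, m.gene_ids, mask, 0.8) == 1.0

    def test_one_sixth_toy(self, rng):
        """4 genes, all 6 pairs correlated inside the mask, exactly 1 outside."""
        inside = rng.normal(scale=3, size=5)
        out_ab = rng.normal(scale=3, size=5)
        values = np.vstack([
            np.concatenate([1.0 * inside, out_ab]),            # a
            np.concatenate([2.0 * inside + 1, 1.5 * out_ab]),  # b: tracks a outside
            np.concatenate([-1.5 * inside, rng.normal(size=5)]),
            np.concatenate([0.7 * inside + 2, rng.normal(size=5)]),
        ])
        m = make_matrix(values)
        mask = SampleMask.from_indices(range(5), 10)
        n_set = correlated_pairs_oracle(values, range(4), list(range(5)), 0.8)
        m_set = correlated_pairs_oracle(values, range(4), list(range(5, 10)), 0.8)
        assert len(n_set) == 6 and len(m_set) == 1  # construction check
        assert bscore(m, m.gene_ids, mask, 0.8) == pytest.approx(1 / 6)

    def test_matches_oracle_and_bounds(self, rng):
        for _ in range(10):
            m = make_matrix(rng.normal(size=(5, 9)))
            idx = sorted(rng.choice(9, size=5, replace=False).tolist())
            mask = SampleMask.from_indices(idx, 9)
            got = bscore(m, m.gene_ids, mask, 0.8)
            assert got == bscore_oracle(m.values, range(5), idx, 0.8)
            assert 0.0 <= got <= 1.0

    def test_invariant_under_gene_and_sample_permutation(self, rng):
        values = rng.normal(size=(5, 8))
        m = make_matrix(values)
        mask = SampleMask((1, 1, 1, 1, 0, 0, 0, 0))
        ref = bscore(m, m.gene_ids, mask, 0.8)
        # permute genes
        assert bscore(m, m.gene_ids[::-1], mask, 0.8) == ref
        # permute samples within the mask and within the complement
        perm = [3, 1, 0, 2, 6, 7, 4, 5]
        m2 = make_matrix(values[:, perm])
        assert bscore(m2, m2.gene_ids, mask, 0.8) == ref

    def test_complete_pair_set_closed_form(self, rng):
        """For an all-pairs-correlated gene set, BScore = |M| / C(|I|, 2)."""
        base = rng.normal(scale=3, size=6)
        m = make_matrix(affine_copies(base, [(1, 0), (2, -1), (1.2, 2), (0.8, 0)],
                                      rng=rng, pad=6))
        mask = SampleMask.from_indices(range(6), 12)
        n_set = correlated_pairs(m, m.gene_ids, mask, 0.8).pairs
        m_set = correlated_pairs(m, m.gene_ids, mask.complement(), 0.8).pairs
        assert len(n_set) == 6
        assert bscore(m, m.gene_ids, mask, 0.8) == pytest.approx(len(m_set) / 6)
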