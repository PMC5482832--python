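import numpy as np
import pytest

from ccsbiclust.core import Bicluster, SampleMask
from ccsbiclust.io import write_biclusters
from ccsbiclust.search import (
    SearchConfig,
    find_bicluster_for_base,
    grow_bicluster,
    merge_biclusters,
    run_ccs,
    sort_by_variability,
)
from .conftest import make_matrix
from .oracle import find_bicluster_oracle, grow_oracle, merge_oracle


def run_base_search(matrix, config):
    """All per-base biclusters of a variability-sorted matrix."""
    out = []
    for i in range(matrix.n_genes):
        bc = find_bicluster_for_base(matrix, i, config)
        if bc is not None:
            out.append(bc)
    return out


class TestSortByVariability:
    def test_orders_by_std_descending(self):
        m = make_matrix([[0, 0.1, 0, 0.1], [0, 5, 0, 5], [0, 2, 0, 2]])
        assert sort_by_variability(m).gene_ids == ["g1", "g2", "g0"]

    def test_stable_on_ties(self):
        m = make_matrix([[0, 1, 0, 1], [5, 6, 5, 6], [2, 4, 2, 4]])
        assert sort_by_variability(m).gene_ids == ["g2", "g0", "g1"]

    def test_matches_argsort_oracle(self, rng):
        m = make_matrix(rng.normal(size=(50, 8)) * rng.uniform(0.1, 5, (50, 1)))
        got = sort_by_variability(m).gene_ids
        stds = [float(np.std(m.row(g))) for g in m.gene_ids]
        expected = [m.gene_ids[i] for i in
                    sorted(range(50), key=lambda i: (-stds[i], i))]
        assert got == expected


class TestGrowBicluster:
    def test_only_seed_when_nothing_else_correlates(self, rng):
        m = make_matrix(np.vstack([
            rng.normal(size=8), np.arange(8.0), 2 * np.arange(8.0) + 1,
            rng.normal(size=8),
        ]))
        got = grow_bicluster(m, ("g1", "g2"), SampleMask.full(8), 0.99)
        assert got == ("g1", "g2")

    def test_affine_family_fully_recovered(self, rng):
        base = rng.normal(scale=2, size=7)
        rows = [a * base + c for a, c in
                [(1, 0), (2, 1), (-1, 3), (0.5, -2), (1.5, 0)]]
        m = make_matrix(np.vstack(rows))
        got = grow_bicluster(m, ("g0", "g1"), SampleMask.full(7), 0.9)
        assert got == tuple(m.gene_ids)

    def test_matches_scan_order_oracle(self, affine_block_matrix):
        m, block_rows, block_cols = affine_block_matrix
        sm = sort_by_variability(m)
        mask = SampleMask.from_indices(block_cols, m.n_samples)
        seed = (sm.gene_ids[0], sm.gene_ids[1])
        got = grow_bicluster(sm, seed, mask, 0.8)
        expected = grow_oracle(sm.values, 0, 1, block_cols, 0.8)
        assert got == tuple(sm.gene_ids[p] for p in expected)


class TestFindBiclusterForBase:
    def test_uncorrelated_base_returns_none(self, rng):
        m = sort_by_variability(make_matrix(rng.normal(size=(8, 10))))
        cfg = SearchConfig(theta=0.99, adaptive_theta=False)
        assert find_bicluster_for_base(m, 0, cfg) is None

    @pytest.mark.parametrize("min_genes", [2, 3])
    def test_agrees_with_literal_replay(self, rng, min_genes):
        """Exhaustive-enumeration oracle replaying the per-base search."""
        cfg = SearchConfig(theta=0.8, min_genes=min_genes, adaptive_theta=False)
        checked = 0
        for _ in range(30):
            m = sort_by_variability(make_matrix(rng.normal(size=(12, 10))))
            for i in range(3):
                got = find_bicluster_for_base(m, i, cfg)
                exp = find_bicluster_oracle(
                    m.values, m.gene_means, i, 0.8, min_genes=min_genes)
                if exp is None:
                    assert got is None
                    continue
                rows, samples, k, score = exp
                assert got is not None
                assert got.genes == tuple(m.gene_ids[p] for p in rows)
                assert got.samples == tuple(m.sample_ids[s] for s in samples)
                assert got.bscore == score
                checked += 1
        assert checked >= 5  # the replay must actually exercise found biclusters

    def test_every_candidate_respects_config_bounds(self, affine_block_matrix):
        m, _, _ = affine_block_matrix
        sm = sort_by_variability(m)
        for min_samples in (3, 5):
            cfg = SearchConfig(adaptive_theta=False, min_samples=min_samples)
            for i in range(6):
                bc = find_bicluster_for_base(sm, i, cfg)
                if bc is None:
                    continue
                assert bc.n_samples >= min_samples
                assert bc.n_genes >= cfg.min_genes
                assert bc.bscore < cfg.bscore_threshold
                assert bc.base_gene == sm.gene_ids[i]


class TestMergeBiclusters:
    def _bc(self, m, rows, cols, bscore=0.0):
        return Bicluster(
            genes=tuple(m.gene_ids[r] for r in rows),
            samples=tuple(m.sample_ids[c] for c in cols),
            bscore=bscore,
        )

    def test_gene_disjoint_survive_unchanged(self, rng):
        m = make_matrix(rng.normal(size=(10, 8)))
        a = self._bc(m, [0, 1, 2], [0, 1, 2, 3])
        b = self._bc(m, [5, 6, 7], [4, 5, 6, 7])
        out = merge_biclusters(m, [a, b], SearchConfig())
        assert [(bc.genes, bc.samples) for bc in out] == [
            (a.genes, a.samples), (b.genes, b.samples)]

    def test_identical_biclusters_collapse(self, rng):
        base = rng.normal(scale=3, size=4)
        values = np.vstack([a * base for a in (1.0, 2.0, 1.5)])
        values = np.hstack([values, rng.normal(size=(3, 6))])
        m = make_matrix(values)
        a = self._bc(m, [0, 1, 2], [0, 1, 2, 3])
        out = merge_biclusters(m, [a, a], SearchConfig())
        assert len(out) == 1

    def test_agrees_with_literal_replay(self, rng):
        cfg = SearchConfig(theta=0.8, adaptive_theta=False)
        for _ in range(20):
            m = sort_by_variability(make_matrix(rng.normal(size=(12, 10))))
            found = run_base_search(m, cfg)
            if not found:
                continue
            got = merge_biclusters(m, found, cfg)
            replay = merge_oracle(
                m.values,
                [([m.gene_index(g) for g in bc.genes],
                  [m.sample_index(s) for s in bc.samples]) for bc in found],
                0.8)
            assert len(got) == len(replay)
            for bc, (rows, samples, score) in zip(got, replay):
                assert sorted(m.gene_index(g) for g in bc.genes) == rows
                assert sorted(m.sample_index(s) for s in bc.samples) == samples
                assert bc.bscore == score


class TestRunCcs:
    def test_pure_noise_high_theta_yields_nothing_substantial(self, rng):
        """i.i.d. Gaussian noise carries no reportable coexpression structure.

        With sample sets of at least 5, a 0.99 correlation bound is
        unreachable for noise and the result is empty.  At the minimum
        sample-set size of 3, near-unit correlations between 3 points are
        weakly constrained, so occasional few-sample artifacts slip through;
        anything reported must still honor the BScore bound and be tiny.
        """
        m = make_matrix(rng.normal(size=(20, 10)))
        res = run_ccs(m, SearchConfig(theta=0.99, adaptive_theta=False,
                                      min_samples=5))
        assert len(res) == 0
        assert res.theta_used == 0.99
        res3 = run_ccs(m, SearchConfig(theta=0.99, adaptive_theta=False))
        for bc in res3:
            assert bc.bscore < 0.01

    def test_planted_family_recovered(self, affine_block_matrix):
        m, block_rows, _ = affine_block_matrix
        planted = {m.gene_ids[r] for r in block_rows}
        res = run_ccs(m, SearchConfig(theta=0.8, adaptive_theta=False))
        assert any(planted <= set(bc.genes) for bc in res)

    def test_all_pairs_property_premerge_and_bscore_final(self, affine_block_matrix):
        from ccsbiclust.core import masked_pearson
        from ccsbiclust.scoring import bscore as bscore_api

        m, _, _ = affine_block_matrix
        sm = sort_by_variability(m)
        cfg = SearchConfig(theta=0.8, adaptive_theta=False)
        found = run_base_search(sm, cfg)
        assert found
        for bc in found:
            mask = bc.sample_mask(sm)
            for a in range(len(bc.genes)):
                for b in range(a + 1, len(bc.genes)):
                    r = masked_pearson(sm.row(bc.genes[a]), sm.row(bc.genes[b]),
                                       mask)
                    assert abs(r) > 0.8
        for bc in merge_biclusters(sm, found, cfg):
            assert bscore_api(sm, bc.genes, bc.sample_mask(sm), 0.8) < 0.01

    def test_adaptive_theta_decrements_until_found(self, rng):
        base = rng.normal(scale=2, size=10)
        rows = [base, 0.9 * base + rng.normal(scale=0.9, size=10),
                1.1 * base + rng.normal(scale=0.9, size=10)]
        rows += [rng.normal(size=10) for _ in range(5)]
        m = make_matrix(np.vstack(rows))
        res = run_ccs(m, SearchConfig(theta=0.99, adaptive_theta=True))
        # either something was eventually found below the initial theta, or
        # every theta down to the floor was tried
        if len(res):
            assert res.theta_used < 0.99
        else:
            assert res.theta_used == pytest.approx(0.04)

    def test_deterministic_and_order_independent(self, affine_block_matrix,
                                                 rng, tmp_path):
        m, _, _ = affine_block_matrix
        cfg = SearchConfig(theta=0.8, adaptive_theta=False)
        res1 = run_ccs(m, cfg)
        res2 = run_ccs(m, cfg)
        # byte-identical serialization of two sequential runs
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_biclusters(res1, p1)
        write_biclusters(res2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        # shuffled (parallel-order) execution over base genes gives the same set
        sm = sort_by_variability(m)
        order = list(range(sm.n_genes))
        rng.shuffle(order)
        by_base = {i: find_bicluster_for_base(sm, i, cfg) for i in order}
        found = [by_base[i] for i in sorted(by_base) if by_base[i] is not None]
        shuffled = merge_biclusters(sm, found, cfg)
        p3 = tmp_path / "c.json"
        write_biclusters(
            type(res1)(biclusters=shuffled, theta_used=res1.theta_used,
                       source=res1.source), p3)
        assert p3.read_bytes() == p1.read_bytes()

    def test_growth_monotone_in_theta(self, affine_block_matrix):
        m, _, block_cols = affine_block_matrix
        sm = sort_by_variability(m)
        mask = SampleMask.from_indices(block_cols, m.n_samples)
        seed = (sm.gene_ids[0], sm.gene_ids[1])
        lo = set(grow_bicluster(sm, seed, mask, 0.8))
        hi = set(grow_bicluster(sm, seed, mask, 0.95))
        assert hi <= lo
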