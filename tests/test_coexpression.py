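"""Weighted correlation, redundancy weights, ranks and mutual ranks."""

import numpy as np
import pytest
from scipy import stats

import coexmap as cm
from coexmap.models import CoexmapError
from support import brute_force_map, random_expression, weighted_pearson_loops


class TestSampleSimilarity:
    def test_duplicated_column_is_one(self):
        expr = random_expression(0, 10, 4)
        expr.values[:, 3] = expr.values[:, 0]
        S = cm.sample_similarity(expr)
        assert S[0, 3] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_unit_diagonal(self):
        S = cm.sample_similarity(random_expression(1, 15, 6))
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)

    def test_hand_computed_3x3(self):
        values = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 1.0], [3.0, 5.0, 6.0]])
        expr = cm.ExpressionMatrix(["a", "b", "c"], ["s0", "s1", "s2"], values)
        S = cm.sample_similarity(expr)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            expected = stats.pearsonr(values[:, i], values[:, j]).statistic
            assert S[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_error(self):
        expr = random_expression(2, 5, 3)
        expr.values[:, 1] = 0.2
        with pytest.raises(CoexmapError, match="s001"):
            cm.sample_similarity(expr)


class TestRedundancyWeights:
    def test_no_redundancy_gives_unit_weights(self):
        S = np.eye(4)
        w = cm.redundancy_weights(S, 0.9)
        assert w.weights.tolist() == [1.0] * 4

    def test_k_copies_get_inverse_k(self):
        # three identical samples plus one unrelated
        S = np.eye(4)
        for i in (0, 1, 2):
            for j in (0, 1, 2):
                S[i, j] = 1.0
        w = cm.redundancy_weights(S, 0.95)
        assert w.weights.tolist() == [1 / 3, 1 / 3, 1 / 3, 1.0]

    def test_matches_per_row_threshold_count(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(-1, 1, size=(5, 5))
        S = (A + A.T) / 2
        np.fill_diagonal(S, 1.0)
        w = cm.redundancy_weights(S, 0.7)
        for i in range(5):
            n_i = sum(1 for j in range(5) if S[i, j] >= 0.7)
            assert w.weights[i] == pytest.approx(1.0 / n_i)

    def test_tau_above_one_error(self):
        with pytest.raises(ValueError):
            cm.redundancy_weights(np.eye(3), 1.5)


class TestWeightedPearson:
    def test_uniform_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = cm.weighted_pearson(x, y, np.ones(20))
        assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_anticorrelated_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        w = np.array([0.3, 1.0, 2.0, 0.1])
        assert cm.weighted_pearson(x, -x, w) == pytest.approx(-1.0, abs=1e-12)

    def test_formula_oracle(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        w = [0.4, 0.1, 0.1, 0.4]
        assert cm.weighted_pearson(x, y, w) == pytest.approx(
            weighted_pearson_loops(x, y, w), abs=1e-12
        )

    def test_weight_rescale_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        w = rng.uniform(0.1, 2.0, size=10)
        assert cm.weighted_pearson(x, y, w) == pytest.approx(
            cm.weighted_pearson(x, y, 13.7 * w), abs=1e-12
        )

    def test_zero_variance_error(self):
        with pytest.raises(CoexmapError):
            cm.weighted_pearson([1, 1, 1], [1, 2, 3], [1, 1, 1])


class TestBuildMap:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_equals_bruteforce_oracle(self, seed):
        expr = random_expression(seed, 8, 10)
        weights = cm.redundancy_weights(cm.sample_similarity(expr), 0.9, expr.sample_ids)
        cmap = cm.build_map(expr, weights)
        r, rank, mr = brute_force_map(expr, weights)
        ids = expr.feature_ids
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                assert cmap.r(a, b) == pytest.approx(r[(a, b)], abs=1e-10)
                assert cmap.rank_forward(a, b) == rank[(a, b)]
                assert cmap.mutual_rank(a, b) == pytest.approx(mr[(a, b)])

    def test_four_feature_hand_fixture(self):
        """N=4 fixture small enough to enumerate by hand: g0/g1 nearly
        identical, g2 their mirror, g3 unrelated."""
        values = np.array(
            [
                [0.1, 0.2, 0.3, 0.4, 0.5],
                [0.11, 0.2, 0.3, 0.4, 0.49],
                [0.5, 0.4, 0.3, 0.2, 0.1],
                [0.3, 0.1, 0.4, 0.2, 0.3],
            ]
        )
        expr = cm.ExpressionMatrix(
            ["g0", "g1", "g2", "g3"], [f"s{j}" for j in range(5)], values
        )
        cmap = cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))
        # g0's partners by r: g1 (~1), g3, g2 (-1); and symmetrically
        assert cmap.rank_forward("g0", "g1") == 1
        assert cmap.rank_forward("g1", "g0") == 1
        assert cmap.mutual_rank("g0", "g1") == 1.0
        assert cmap.rank_forward("g0", "g2") == 3
        # g2 is the exact mirror of g0 (y = 0.6 - x): r is exactly -1
        entry = cm.pair_lookup(cmap, "g0", "g2")
        assert entry.r == pytest.approx(-1.0, abs=1e-12)

    def test_mutual_rank_symmetry_and_bounds(self, module_map):
        cmap, *_ = module_map
        rng = np.random.default_rng(0)
        ids = cmap.feature_ids
        n = len(ids)
        for _ in range(200):
            i, j = rng.choice(n, size=2, replace=False)
            a, b = ids[i], ids[j]
            assert cmap.mutual_rank(a, b) == cmap.mutual_rank(b, a)
            assert 1 <= cmap.rank_forward(a, b) <= n - 1

    def test_forward_ranks_are_permutation(self):
        expr = random_expression(5, 12, 8)
        cmap = cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))
        for i in range(12):
            row = np.delete(cmap.rank_matrix[i], i)
            assert sorted(row.tolist()) == list(range(1, 12))

    def test_uniform_weight_reduction_matches_corrcoef(self):
        expr = random_expression(6, 10, 9)
        cmap = cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))
        ref = np.corrcoef(expr.values)
        assert np.allclose(cmap.r_matrix, ref, atol=1e-12)

    def test_duplicate_sample_neutrality(self):
        """Adding an exact copy of a sample and down-weighting the pair
        reproduces the unit-weight map on the original samples."""
        expr = random_expression(7, 9, 8)
        base = cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))
        dup_vals = np.hstack([expr.values, expr.values[:, [0]]])
        dup = cm.ExpressionMatrix(
            expr.feature_ids, expr.sample_ids + ["s000_dup"], dup_vals
        )
        weights = np.ones(9)
        weights[0] = weights[8] = 0.5  # the two copies share their weight
        sw = cm.SampleWeights(dup.sample_ids, weights)
        dup_map = cm.build_map(dup, sw)
        assert np.allclose(dup_map.r_matrix, base.r_matrix, atol=1e-12)

    def test_hub_deprioritized_by_mutual_rank(self):
        """Tight-module partners reach lower MR with each other than with a
        hub that is strongly but uniformly correlated with everything."""
        rng = np.random.default_rng(11)
        n_samples = 40
        f1 = rng.normal(size=n_samples)
        f2 = rng.normal(size=n_samples)
        rows, ids = [], []
        for m, f in ((1, f1), (2, f2)):
            for g in range(4):
                rows.append(f + 0.05 * rng.normal(size=n_samples))
                ids.append(f"m{m}g{g}")
        hub = (f1 + f2) / np.sqrt(2) + 0.1 * rng.normal(size=n_samples)
        rows.append(hub)
        ids.append("hub")
        values = np.array(rows)
        values = values - values.min() + 0.1  # expression must be non-negative
        expr = cm.ExpressionMatrix(ids, [f"s{j}" for j in range(n_samples)], values)
        cmap = cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))
        # every module gene ranks all of its module partners ahead of the hub
        for a in range(4):
            hub_rank = cmap.rank_forward(f"m1g{a}", "hub")
            partner_ranks = [
                cmap.rank_forward(f"m1g{a}", f"m1g{b}") for b in range(4) if b != a
            ]
            assert max(partner_ranks) < hub_rank
        within = [
            cmap.mutual_rank(f"m1g{a}", f"m1g{b}")
            for a in range(4)
            for b in range(4)
            if a < b
        ]
        with_hub = [cmap.mutual_rank(f"m1g{a}", "hub") for a in range(4)]
        assert np.median(within) < np.median(with_hub)

    def test_constant_feature_error(self):
        expr = random_expression(8, 5, 6)
        expr.values[2, :] = 0.2
        with pytest.raises(CoexmapError, match="g002"):
            cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))

    def test_geometric_mr_rule(self):
        expr = random_expression(9, 6, 8)
        cmap = cm.build_map(
            expr, cm.SampleWeights.uniform(expr.sample_ids), mr_rule="geometric"
        )
        a, b = "g000", "g001"
        expected = np.sqrt(cmap.rank_forward(a, b) * cmap.rank_forward(b, a))
        assert cmap.mutual_rank(a, b) == pytest.approx(expected)


class TestPairLookup:
    def test_stored_pair_matches_neighbor_entry(self, module_map):
        cmap, *_ = module_map
        fid = cmap.feature_ids[0]
        top = cmap.neighbors(fid, 1)[0]
        entry = cm.pair_lookup(cmap, fid, top.neighbor_id)
        assert (entry.r, entry.mutual_rank) == (top.r, top.mutual_rank)

    def test_self_pair_error(self, module_map):
        cmap, *_ = module_map
        with pytest.raises(ValueError):
            cm.pair_lookup(cmap, "g0000", "g0000")

    def test_r_matches_direct_weighted_pearson(self, module_map):
        cmap, truth, expr, weights = module_map
        i, j = 3, 77
        direct = cm.weighted_pearson(
            expr.values[i], expr.values[j], weights.weights
        )
        entry = cm.pair_lookup(cmap, expr.feature_ids[i], expr.feature_ids[j])
        assert entry.r == pytest.approx(direct, abs=1e-10)

    def test_unknown_id_suggests_alternatives(self, module_map):
        cmap, *_ = module_map
        with pytest.raises(KeyError, match="nearest"):
            cmap.r("gXXXX", "g0001")


class TestSerialization:
    def test_roundtrip_preserves_neighbor_lists(self, tmp_path):
        expr = random_expression(10, 10, 8)
        cmap = cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))
        cm.save_map(cmap, tmp_path / "map")
        loaded = cm.load_map(tmp_path / "map")
        assert loaded.feature_ids == cmap.feature_ids
        assert loaded.n_samples == cmap.n_samples
        for fid in cmap.feature_ids:
            built = cmap.neighbors(fid)
            stored = loaded.neighbors(fid)
            assert [e.neighbor_id for e in built] == [e.neighbor_id for e in stored]
            for x, y in zip(built, stored):
                assert y.r == pytest.approx(x.r, rel=1e-9)
                assert (y.rank_forward, y.rank_backward) == (
                    x.rank_forward,
                    x.rank_backward,
                )

    def test_stored_map_rank_lookup(self, tmp_path):
        expr = random_expression(11, 6, 8)
        cmap = cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))
        cm.save_map(cmap, tmp_path / "map")
        loaded = cm.load_map(tmp_path / "map")
        top = cmap.neighbors("g000", 1)[0]
        assert loaded.rank_forward("g000", top.neighbor_id) == top.rank_forward
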