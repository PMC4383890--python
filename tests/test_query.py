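"""Guilt-by-association queries, enrichment, partner overlap."""

import itertools

import numpy as np
import pytest

import coexmap as cm
from support import hypergeom_tail_enumeration, random_expression, tiny_map


class TestCorrelationPvalue:
    def test_zero_r_gives_p_one(self):
        assert cm.correlation_pvalue(0.0, 30).p_value == pytest.approx(1.0)

    def test_against_independent_t_tail(self):
        # frozen from R: cor.test-style t transform, r=0.5, n=30, df=28
        test = cm.correlation_pvalue(0.5, 30)
        assert test.t_statistic == pytest.approx(3.05505046330389, abs=1e-10)
        assert test.p_value == pytest.approx(0.00489993366706809, rel=1e-10)

    def test_monotone_in_r(self):
        assert (
            cm.correlation_pvalue(0.6, 30).p_value
            < cm.correlation_pvalue(0.4, 30).p_value
        )

    def test_perfect_correlation_flagged(self):
        test = cm.correlation_pvalue(1.0, 30)
        assert test.p_value == 0.0 and test.degenerate

    def test_bonferroni_cutoff(self):
        test = cm.correlation_pvalue(0.5, 30, n_features=44248)
        assert test.bonferroni_cutoff == pytest.approx(0.05 / 44248)

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            cm.correlation_pvalue(0.5, 3)


class TestTopFractionSize:
    @pytest.mark.parametrize(
        "n,frac,expected",
        [
            (114_936, 0.05, 5_747),
            (100, 0.05, 5),
            (1, 0.05, 1),
            (63, 0.10, 7),  # 6.3 -> ceil
        ],
    )
    def test_sizes(self, n, frac, expected):
        assert cm.top_fraction_size(n, frac) == expected

    def test_nonpositive_fraction_error(self):
        with pytest.raises(ValueError):
            cm.top_fraction_size(100, 0.0)


class TestEnrich:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_bg = int(rng.integers(10, 61))
            background = {f"g{i}" for i in range(n_bg)}
            n_q = int(rng.integers(1, n_bg))
            query = set(rng.choice(sorted(background), size=n_q, replace=False))
            k_term = int(rng.integers(1, n_bg))
            term = set(rng.choice(sorted(background), size=k_term, replace=False))
            rows = cm.enrich(query, background, {"T": term})
            (row,) = rows
            expected = (
                1.0
                if row.query_hits == 0
                else hypergeom_tail_enumeration(
                    row.query_hits, n_bg, k_term, n_q
                )
            )
            assert row.p == pytest.approx(expected, rel=1e-9)

    def test_term_equals_query(self):
        background = {f"g{i}" for i in range(30)}
        query = {f"g{i}" for i in range(3)}
        rows = cm.enrich(query, background, {"T": set(query)})
        assert rows[0].p == pytest.approx(
            hypergeom_tail_enumeration(3, 30, 3, 3), rel=1e-12
        )

    def test_disjoint_term_p_one(self):
        background = {f"g{i}" for i in range(20)}
        rows = cm.enrich({"g0"}, background, {"T": {"g10", "g11"}})
        assert rows[0].p == 1.0

    def test_query_equals_background_saturates(self):
        background = {f"g{i}" for i in range(10)}
        rows = cm.enrich(background, background, {"T": {"g1", "g2"}})
        assert all(r.p == pytest.approx(1.0) for r in rows)

    def test_bonferroni_bounds(self):
        background = {f"g{i}" for i in range(40)}
        annotations = {f"T{j}": {f"g{j}", f"g{j+1}"} for j in range(10)}
        rows = cm.enrich({"g0", "g1", "g2"}, background, annotations)
        for row in rows:
            assert row.p <= row.p_bonferroni <= 1.0

    def test_empty_background_error(self):
        with pytest.raises(ValueError):
            cm.enrich(set(), set(), {"T": {"a"}})

    def test_query_outside_background_error(self):
        with pytest.raises(ValueError):
            cm.enrich({"x"}, {"a", "b"}, {})


class TestQuerySingle:
    def test_planted_module_members_recovered(self, module_map):
        cmap, truth, *_ = module_map
        members = [g for g, m in truth.modules.items() if m == 2]
        report = cm.query_single(cmap, members[0])
        top_ids = {e.neighbor_id for e in report.top_genes}
        assert set(members[1:]) <= top_ids

    def test_empty_tf_list_no_error(self, module_map):
        cmap, *_ = module_map
        report = cm.query_single(cmap, "g0000", tf_ids=set())
        assert report.top_tfs == []

    def test_tf_filtering(self, module_map):
        cmap, *_ = module_map
        tfs = {"g0001", "g0002"}
        report = cm.query_single(cmap, "g0000", tf_ids=tfs)
        assert {e.neighbor_id for e in report.top_tfs} <= tfs

    def test_small_map_truncates(self):
        cmap = tiny_map(seed=1, n=6)
        report = cm.query_single(cmap, "g000")
        assert len(report.top_genes) == 5

    def test_caps_respected(self, module_map):
        cmap, *_ = module_map
        cfg = cm.QueryConfig(n_top_genes=7, n_top_tfs=2, n_enrichment_terms=1)
        annotations = {"T1": set(cmap.feature_ids[:30]), "T2": set(cmap.feature_ids[30:60])}
        report = cm.query_single(
            cmap, "g0000", tf_ids=set(cmap.feature_ids[:10]), annotations=annotations, cfg=cfg
        )
        assert len(report.top_genes) == 7
        assert len(report.top_tfs) <= 2
        assert len(report.enrichment) <= 1

    def test_enrichment_detects_module_annotation(self, module_map):
        """A term annotating exactly one planted module is the top
        enrichment hit when querying a member of that module."""
        cmap, truth, *_ = module_map
        module0 = {g for g, m in truth.modules.items() if m == 0}
        decoy = {g for g, m in truth.modules.items() if m == 1}
        annotations = {"module0_term": module0, "decoy": decoy}
        member = sorted(module0)[0]
        report = cm.query_single(cmap, member, annotations=annotations)
        assert report.enrichment
        assert report.enrichment[0].term == "module0_term"
        assert report.enrichment[0].p < 1e-6

    def test_negative_list_sorted_ascending(self, module_map):
        cmap, *_ = module_map
        report = cm.query_single(cmap, "g0000")
        rs = [e.r for e in report.negative]
        assert rs == sorted(rs)

    def test_unknown_id_error(self, module_map):
        cmap, *_ = module_map
        with pytest.raises(KeyError):
            cm.query_single(cmap, "nope")

    def test_deterministic(self, module_map):
        cmap, *_ = module_map
        a = cm.query_single(cmap, "g0000")
        b = cm.query_single(cmap, "g0000")
        assert [e.neighbor_id for e in a.top_genes] == [
            e.neighbor_id for e in b.top_genes
        ]


class TestQuerySet:
    def test_single_seed_reduces_to_forward_rank_order(self, module_map):
        cmap, *_ = module_map
        ranked, _ = cm.query_set(cmap, ["g0000"], method="mean_rank")
        by_rank = sorted(
            (f for f in cmap.feature_ids if f != "g0000"),
            key=lambda f: (cmap.rank_forward("g0000", f), f),
        )
        assert [c for c, _ in ranked] == by_rank

    def test_planted_module_recovery(self, module_map):
        cmap, truth, *_ = module_map
        module3 = sorted(g for g, m in truth.modules.items() if m == 3)
        seeds, rest = module3[:5], set(module3[5:])
        ranked, missing = cm.query_set(cmap, seeds)
        assert missing == []
        assert {c for c, _ in ranked[:15]} == rest

    def test_vote_score_bound_and_seed_order_invariance(self, module_map):
        cmap, truth, *_ = module_map
        module1 = sorted(g for g, m in truth.modules.items() if m == 1)
        seeds = module1[:5]
        a, _ = cm.query_set(cmap, seeds, method="vote")
        b, _ = cm.query_set(cmap, list(reversed(seeds)), method="vote")
        assert a == b
        assert all(score <= len(seeds) for _, score in a)
        # a fellow module member sits in every seed's top-5% list
        top_candidate, top_score = a[0]
        assert top_score == len(seeds)
        assert top_candidate in module1

    def test_mean_rank_leave_one_out_bound(self, module_map):
        """Removing one seed moves a candidate's mean rank by at most that
        seed's contribution spread."""
        cmap, truth, *_ = module_map
        module4 = sorted(g for g, m in truth.modules.items() if m == 4)
        seeds = module4[:5]
        full, _ = cm.query_set(cmap, seeds)
        full_scores = dict(full)
        n = cmap.n_features
        reduced, _ = cm.query_set(cmap, seeds[:-1])
        for cand, score in reduced[:50]:
            if cand not in full_scores:  # the removed seed rejoins the pool
                continue
            # |mean_k-1 - mean_k| <= max rank / k
            assert abs(score - full_scores[cand]) <= n / len(seeds) + 1e-9

    def test_missing_seeds_reported(self, module_map):
        cmap, *_ = module_map
        ranked, missing = cm.query_set(cmap, ["g0000", "zzz"])
        assert missing == ["zzz"]

    def test_all_seeds_missing_error(self, module_map):
        cmap, *_ = module_map
        with pytest.raises(ValueError):
            cm.query_set(cmap, ["zzz"])


class TestPartnerOverlap:
    def test_duplicate_features_full_overlap(self):
        expr = random_expression(3, 30, 15)
        values = expr.values.copy()
        values[1] = values[0] * 1.7  # scaled copy: identical correlations
        dup = cm.ExpressionMatrix(expr.feature_ids, expr.sample_ids, values)
        cmap = cm.build_map(dup, cm.SampleWeights.uniform(dup.sample_ids))
        out = cm.partner_overlap(cmap, "g000", "g001", frac=0.2)
        assert out["fraction"] == pytest.approx(1.0)

    def test_planted_same_module_pair_overlaps(self, module_map):
        cmap, truth, *_ = module_map
        module0 = sorted(g for g, m in truth.modules.items() if m == 0)
        out = cm.partner_overlap(cmap, module0[0], module0[1], frac=0.1)
        assert out["fraction"] > 0.5

    def test_independent_features_overlap_near_fraction(self):
        expr = random_expression(12, 120, 60)
        cmap = cm.build_map(expr, cm.SampleWeights.uniform(expr.sample_ids))
        fracs = [
            cm.partner_overlap(cmap, a, b, frac=0.1)["fraction"]
            for a, b in itertools.combinations(expr.feature_ids[:12], 2)
        ]
        # null expectation ~ frac; allow a generous band around it
        assert 0.0 <= np.mean(fracs) < 0.35

    def test_same_feature_error(self, module_map):
        cmap, *_ = module_map
        with pytest.raises(ValueError):
            cm.partner_overlap(cmap, "g0000", "g0000")

    def test_list_size_uses_full_map_n(self, module_map):
        cmap, *_ = module_map
        out = cm.partner_overlap(cmap, "g0000", "g0001", frac=0.05)
        assert out["list_size"] == cm.top_fraction_size(cmap.n_features, 0.05)
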