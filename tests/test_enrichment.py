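"""Ranked/DEG lists, the weighted KS statistic, GSEA-preranked, ORA, BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from contraset import (
    GseaParams,
    RankedList,
    bh_adjust,
    create_deg_list,
    create_ranked_list,
    enrichment_score,
    gsea_preranked,
    make_ranked_fixture,
    ora_hypergeometric,
)
from contraset.enrichment import DegList, _es_from_positions
from contraset.errors import (
    EmptyDegListError,
    EmptyIntersectionError,
    MissingColumnError,
    NoSetsPassSizeFilterError,
    SetEqualsUniverseError,
    ValueOutOfRangeError,
)
from oracles import (
    bh_stepup,
    hypergeom_by_enumeration,
    hypergeom_upper_tail,
    running_sum_es,
)
from test_geneset_extract import _gene_dataset


def _ranked(scores, gene_ids=None):
    gene_ids = gene_ids or list(range(1, len(scores) + 1))
    entries = sorted(zip(gene_ids, map(float, scores)),
                     key=lambda t: (-t[1], t[0]))
    return RankedList(entries=entries, metric="S")


class TestRankedAndDegLists:
    def test_ranked_list_sorted_descending_with_deterministic_ties(self):
        gd = _gene_dataset([0.1] * 4, [0.5] * 4, s=[1.0, 3.0, 1.0, 2.0])
        ranked = create_ranked_list(gd, "C", "S")
        assert ranked.gene_ids == [2, 4, 1, 3]  # ties -> ascending gene_id
        assert ranked.scores[0] == 3.0

    def test_row_permutation_does_not_change_ranking(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 50)
        gd = _gene_dataset(np.sign(s), np.full(50, 0.5), s=s)
        perm = rng.permutation(50)
        gd2 = _gene_dataset(np.sign(s)[perm], np.full(50, 0.5), s=s[perm])
        gd2.gene_ids = list(np.array(gd.gene_ids)[perm])
        gd2.symbols = list(np.array(gd.symbols)[perm])
        assert create_ranked_list(gd, "C").entries == \
            create_ranked_list(gd2, "C").entries

    def test_m_and_s_metrics_differ_when_signs_disagree(self):
        # gene 2 has large M but small S; gene 1 the opposite
        gd = _gene_dataset([0.5, 4.0], [0.5, 0.5], s=[3.0, 0.2])
        assert create_ranked_list(gd, "C", "S").gene_ids == [1, 2]
        assert create_ranked_list(gd, "C", "M").gene_ids == [2, 1]

    def test_missing_metric_column_rejected(self):
        gd = _gene_dataset([1.0], [0.5])
        with pytest.raises(MissingColumnError):
            create_ranked_list(gd, "C", "S")

    def test_deg_list_thresholds(self):
        p = [0.01, 0.2, 0.03, 0.8]
        gd = _gene_dataset([1.0] * 4, p)
        deg = create_deg_list(gd, "C", 0.05)
        assert deg.gene_ids == {1, 3}
        assert deg.universe == {1, 2, 3, 4}
        assert create_deg_list(gd, "C", 1.0).gene_ids == deg.universe
        with pytest.raises(EmptyDegListError):
            create_deg_list(gd, "C", 0.001)


class TestEnrichmentScore:
    def test_singleton_at_top_unweighted_is_one(self):
        ranked = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, rank_at_max, _ = enrichment_score(ranked, [1], p=0.0)
        assert es == 1.0 and rank_at_max == 1

    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    def test_top_block_set_reaches_one(self, p):
        ranked = _ranked(np.linspace(10, 1, 20))
        es, rank_at_max, _ = enrichment_score(ranked, [1, 2, 3, 4, 5], p=p)
        assert es == pytest.approx(1.0, abs=1e-12)
        assert rank_at_max == 5

    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    def test_matches_running_sum_oracle(self, p):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(10, 100))
            k = int(rng.integers(1, min(20, n - 1) + 1))
            ranked = _ranked(np.round(rng.normal(0, 2, n), 4))
            members = list(rng.choice(ranked.gene_ids, size=k, replace=False))
            es, rank_at_max, run = enrichment_score(ranked, members, p=p)
            hit = [g in set(members) for g in ranked.gene_ids]
            es_o, rank_o, walk_o = running_sum_es(
                ranked.scores.tolist(), hit, p)
            assert es == pytest.approx(es_o, abs=1e-12)
            assert rank_at_max == rank_o
            np.testing.assert_allclose(run, walk_o, atol=1e-12)

    def test_es_bounded_and_reversal_negates_unweighted(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = rng.normal(0, 1, n)
            ranked = _ranked(scores)
            members = list(rng.choice(ranked.gene_ids,
                                      size=int(rng.integers(2, 8)),
                                      replace=False))
            es, _, run = enrichment_score(ranked, members, p=0.0)
            assert -1.0 <= es <= 1.0
            rev = RankedList(entries=[(g, -s) for g, s in
                                      reversed(ranked.entries)], metric="S")
            es_rev, _, _ = enrichment_score(rev, members, p=0.0)
            assert abs(es_rev) == pytest.approx(abs(es), abs=1e-12)
            # the sign flips whenever the extreme magnitude is unambiguous
            if abs(run.max() + run.min()) > 1e-9:
                assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_fast_position_formula_agrees_with_full_walk(self):
        rng = np.random.default_rng(31)
        for p in (0.0, 1.0, 2.0):
            n = 80
            ranked = _ranked(rng.normal(0, 2, n))
            abs_p = np.abs(ranked.scores) ** p
            for _ in range(50):
                k = int(rng.integers(1, 15))
                pos = rng.choice(n, size=k, replace=False)
                members = [ranked.gene_ids[i] for i in pos]
                es_full, _, _ = enrichment_score(ranked, members, p=p)
                es_fast = _es_from_positions(pos[None, :], abs_p, n)[0]
                assert es_fast == pytest.approx(es_full, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        ranked = _ranked([3.0, 2.0, 1.0])
        with pytest.raises(EmptyIntersectionError):
            enrichment_score(ranked, [99])
        with pytest.raises(SetEqualsUniverseError):
            enrichment_score(ranked, [1, 2, 3])


class TestGseaPreranked:
    def test_same_seed_is_byte_identical(self):
        ranked, coll, _ = make_ranked_fixture(4, n_genes=200, n_null_sets=5,
                                              planted_sets=1)
        params = GseaParams(n_permutations=100, seed=7, min_size=5)
        a = gsea_preranked(ranked, coll, params)
        b = gsea_preranked(ranked, coll, params)
        assert [(r.set_name, r.es, r.nes, r.nominal_p, r.fdr_q,
                 r.rank_at_max, r.leading_edge) for r in a.results] == \
               [(r.set_name, r.es, r.nes, r.nominal_p, r.fdr_q,
                 r.rank_at_max, r.leading_edge) for r in b.results]

    def test_planted_set_detected_at_low_fdr(self):
        ranked, coll, planted = make_ranked_fixture(
            12, n_genes=1000, n_null_sets=10, set_size=25,
            planted_sets=1, shift=2.0,
        )
        res = gsea_preranked(ranked, coll,
                             GseaParams(n_permutations=1000, seed=1))
        by = res.by_name()
        assert by[planted[0]].fdr_q < 0.05
        assert by[planted[0]].nes > 0

    def test_leading_edge_respects_rank_at_max(self):
        ranked, coll, _ = make_ranked_fixture(8, n_genes=300, n_null_sets=8,
                                              planted_sets=1)
        res = gsea_preranked(ranked, coll,
                             GseaParams(n_permutations=100, seed=2))
        rank_of = {g: i + 1 for i, g in enumerate(ranked.gene_ids)}
        for r in res.results:
            members = set(coll[r.set_name])
            assert set(r.leading_edge) <= members
            for g in r.leading_edge:
                if r.es > 0:
                    assert rank_of[g] <= r.rank_at_max
                else:
                    assert rank_of[g] >= r.rank_at_max

    def test_size_filter_can_reject_everything(self):
        ranked, coll, _ = make_ranked_fixture(3, n_genes=100, n_null_sets=3,
                                              set_size=5)
        with pytest.raises(NoSetsPassSizeFilterError):
            gsea_preranked(ranked, coll,
                           GseaParams(n_permutations=50, seed=0,
                                      min_size=50))


class TestOra:
    def _deg(self, universe_size, deg_ids):
        universe = frozenset(range(1, universe_size + 1))
        return DegList(gene_ids=frozenset(deg_ids), p_threshold=0.05,
                       universe=universe)

    def test_zero_overlap_gives_p_one(self):
        deg = self._deg(20, {1, 2, 3})
        res = ora_hypergeometric(deg, {"s": [10, 11, 12]})
        assert res.results[0].p_value == 1.0

    def test_deg_equals_universe_gives_p_one(self):
        deg = self._deg(10, set(range(1, 11)))
        res = ora_hypergeometric(deg, {"s": [1, 2, 3]})
        assert res.results[0].p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # N=20, K=5, n=6: compare against counting all C(20,6) draws
        deg = self._deg(20, set(range(1, 7)))
        members = [1, 2, 3, 7, 8]  # k = 3
        res = ora_hypergeometric(deg, {"s": members})
        expected = hypergeom_by_enumeration(20, 5, 6, 3)
        assert res.results[0].overlap == 3
        assert res.results[0].p_value == pytest.approx(expected, abs=1e-12)

    def test_matches_rational_oracle_on_random_configs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n_univ = int(rng.integers(5, 26))
            big_k = int(rng.integers(1, n_univ + 1))
            n_draw = int(rng.integers(1, n_univ + 1))
            k = int(rng.integers(0, min(big_k, n_draw) + 1))
            got = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_draw))
            assert got == pytest.approx(
                hypergeom_upper_tail(n_univ, big_k, n_draw, k), abs=1e-12)

    def test_collection_universe_policy(self):
        deg = self._deg(100, {1, 2, 3, 4, 5})
        coll = {"a": list(range(1, 11)), "b": list(range(5, 15))}
        res = ora_hypergeometric(deg, coll, universe_policy="collection")
        assert res.universe_size == 14  # union of collection within contrast
        assert res.universe_policy == "collection"

    def test_fdr_ordering_preserved(self):
        rng = np.random.default_rng(5)
        deg = self._deg(200, set(rng.choice(200, 30, replace=False) + 1))
        coll = {f"s{i}": (rng.choice(200, 20, replace=False) + 1).tolist()
                for i in range(10)}
        res = ora_hypergeometric(deg, coll)
        ps = [r.p_value for r in res.results]
        qs = [r.fdr for r in res.results]
        order_p = np.argsort(ps)
        assert all(np.diff(np.array(qs)[order_p]) >= -1e-12)


class TestBhAdjust:
    def test_single_and_constant_vectors(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup(p.tolist()),
                                       atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueOutOfRangeError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=40))
    def test_stepup_properties_hold_for_arbitrary_vectors(self, p):
        q = np.asarray(bh_adjust(p))
        assert ((q >= -1e-12) & (q <= 1 + 1e-12)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in sorted p
        assert (q[order] >= np.asarray(p)[order] - 1e-12).all()
        np.testing.assert_allclose(q, bh_stepup(list(p)), atol=1e-12)


class TestEnrichmentScoreProperties:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.data())
    def test_es_bounded_and_oracle_exact(self, data):
        n = data.draw(st.integers(min_value=3, max_value=60))
        scores = data.draw(st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=n, max_size=n))
        k = data.draw(st.integers(min_value=1, max_value=n - 1))
        members = data.draw(st.permutations(range(1, n + 1)))[:k]
        p = data.draw(st.sampled_from([0.0, 1.0, 2.0]))
        ranked = _ranked(scores)
        es, rank_at_max, _ = enrichment_score(ranked, members, p=p)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        hit = [g in set(members) for g in ranked.gene_ids]
        es_o, rank_o, _ = running_sum_es(ranked.scores.tolist(), hit, p)
        assert es == pytest.approx(es_o, abs=1e-12)
        assert rank_at_max == rank_o
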