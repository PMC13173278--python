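"""Preranked enrichment running sum, Fisher contingency, count comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from ecoresp.enrich import (
    RankedList,
    count_comparison,
    fisher_family_enrichment,
    gsea_preranked,
    make_ranked_list,
    _running_sum,
)


def _ranked(metrics, ids=None) -> RankedList:
    metrics = np.asarray(metrics, dtype=float)
    ids = ids or [f"i{k}" for k in range(metrics.size)]
    return RankedList(list(ids), metrics, "test")


def _brute_es(metric, member, weight):
    """Independent re-derivation of the weighted KS extremum."""
    n = len(metric)
    k = sum(member)
    denom = sum(abs(m) ** weight for m, h in zip(metric, member) if h)
    run, best = 0.0, 0.0
    for m, h in zip(metric, member):
        if h:
            run += (abs(m) ** weight / denom) if denom > 0 else 1.0 / k
        else:
            run -= 1.0 / (n - k)
        if abs(run) > abs(best):
            best = run
    return best


class TestRankedList:
    def test_signed_neglog10(self):
        r = make_ranked_list(["a", "b"], [0.7, -0.2], [0.001, 0.001])
        assert r.metric[0] == pytest.approx(3.0)
        assert r.metric[1] == pytest.approx(-3.0)
        assert r.item_ids == ["a", "b"]

    def test_literal_signed_one_minus_p_mode(self):
        r = make_ranked_list(["a", "b"], [0.7, -0.2], [0.01, 0.5],
                             metric="signed_one_minus_p")
        assert r.metric[0] == pytest.approx(0.99)
        assert r.metric[1] == pytest.approx(-0.5)

    def test_tie_broken_by_coefficient(self):
        r = make_ranked_list(["a", "b"], [0.2, 0.9], [0.05, 0.05])
        assert r.item_ids == ["b", "a"]

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            r = make_ranked_list(["a"], [1.0], [0.0])
        assert np.isfinite(r.metric[0])


class TestRunningSum:
    def test_top_single_item_es_one(self):
        member = np.array([True, False, False])
        rs = _running_sum(np.array([3.0, 2.0, 1.0]), member, weight=0.0)
        assert rs.tolist() == pytest.approx([1.0, 0.5, 0.0])
        assert rs[0] == pytest.approx(1.0)  # the extremum: ES = 1
        assert rs[-1] == pytest.approx(0.0)  # normalized sum must close at 0

    def test_reversal_negates_es_at_weight_zero(self):
        rng = np.random.default_rng(0)
        metric = np.sort(rng.normal(size=12))[::-1]
        member = rng.random(12) < 0.3
        if not 0 < member.sum() < 12:
            member[:3] = [True, True, False]
        rs = _running_sum(metric, member, 0.0)
        rs_rev = _running_sum(metric[::-1], member[::-1], 0.0)
        es = rs[np.argmax(np.abs(rs))]
        es_rev = rs_rev[np.argmax(np.abs(rs_rev))]
        assert es == pytest.approx(-es_rev)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_es_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        metric = np.sort(rng.normal(size=n))[::-1]
        k = int(rng.integers(1, n))
        member = np.zeros(n, dtype=bool)
        member[rng.choice(n, size=k, replace=False)] = True
        weight = float(rng.choice([0.0, 1.0, 1.5]))
        rs = _running_sum(metric, member, weight)
        es = rs[np.argmax(np.abs(rs))]
        assert es == pytest.approx(
            _brute_es(metric.tolist(), member.tolist(), weight)
        )


class TestGseaPreranked:
    def test_top_block_enriched(self):
        metric = np.linspace(3, -3, 40)
        ranked = _ranked(metric)
        res = gsea_preranked(
            ranked, {"top": [f"i{k}" for k in range(8)]}, n_perm=200, seed=0
        )["top"]
        assert res.es > 0.8
        assert res.p_value < 0.02
        assert res.nes > 1.0
        assert set(res.leading_edge) <= {f"i{k}" for k in range(8)}

    def test_whole_ranking_set_skipped(self):
        ranked = _ranked([2.0, 1.0, -1.0])
        with pytest.warns(UserWarning, match="whole ranking"):
            res = gsea_preranked(ranked, {"all": ["i0", "i1", "i2"]},
                                 n_perm=100, seed=0)
        assert res == {}

    def test_random_sets_calibrated(self):
        rng = np.random.default_rng(4)
        metric = np.sort(rng.normal(size=60))[::-1]
        ranked = _ranked(metric)
        sets = {
            f"s{j}": [f"i{k}" for k in rng.choice(60, size=8, replace=False)]
            for j in range(30)
        }
        res = gsea_preranked(ranked, sets, n_perm=300, seed=5)
        ps = [r.p_value for r in res.values()]
        assert np.mean(np.asarray(ps) < 0.05) < 0.25
        for r in res.values():
            assert np.sign(r.nes) == np.sign(r.es)
            assert r.adj_p >= r.p_value - 1e-12

    def test_adjusted_p_is_bh(self):
        metric = np.linspace(2, -2, 30)
        ranked = _ranked(metric)
        sets = {"a": ["i0", "i1", "i2"], "b": ["i27", "i28", "i29"]}
        res = gsea_preranked(ranked, sets, n_perm=200, seed=1)
        from ecoresp.core_io import bh_adjust

        raw = [res["a"].p_value, res["b"].p_value]
        adj = bh_adjust(raw)
        assert res["a"].adj_p == pytest.approx(adj[0])
        assert res["b"].adj_p == pytest.approx(adj[1])


class TestFisher:
    def test_hand_table_hypergeometric(self):
        presence = {f"a{k}": {"F"} for k in range(10)}
        presence.update({f"b{k}": set() for k in range(10)})
        res = fisher_family_enrichment(
            presence, [f"a{k}" for k in range(10)], [f"b{k}" for k in range(10)]
        )["F"]
        assert res.p_value == pytest.approx(2 / comb(20, 10, exact=True))
        assert res.p_value == pytest.approx(1.083e-5, rel=1e-3)

    def test_identical_frequencies_null(self):
        presence = {f"a{k}": ({"F"} if k < 5 else set()) for k in range(10)}
        presence.update({f"b{k}": ({"F"} if k < 5 else set()) for k in range(10)})
        res = fisher_family_enrichment(
            presence, [f"a{k}" for k in range(10)], [f"b{k}" for k in range(10)]
        )["F"]
        assert res.p_value == pytest.approx(1.0)
        assert res.log_fc == pytest.approx(0.0)
        assert not res.passed

    def test_8_vs_1_passes_defaults(self):
        presence = {f"a{k}": ({"F"} if k < 8 else set()) for k in range(10)}
        presence.update({f"b{k}": ({"F"} if k < 1 else set()) for k in range(10)})
        res = fisher_family_enrichment(
            presence, [f"a{k}" for k in range(10)], [f"b{k}" for k in range(10)]
        )["F"]
        assert res.passed
        assert res.log_fc > 1.0

    def test_group_swap_negates_logfc_preserves_p(self):
        rng = np.random.default_rng(0)
        presence = {
            f"g{k}": {f"F{j}" for j in range(5) if rng.random() < 0.4}
            for k in range(20)
        }
        a = [f"g{k}" for k in range(10)]
        b = [f"g{k}" for k in range(10, 20)]
        fwd = fisher_family_enrichment(presence, a, b)
        rev = fisher_family_enrichment(presence, b, a)
        for fam in fwd:
            assert fwd[fam].p_value == pytest.approx(rev[fam].p_value)
            assert fwd[fam].log_fc == pytest.approx(-rev[fam].log_fc)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            fisher_family_enrichment({"g": {"F"}}, ["g"], ["g"])


class TestCountComparison:
    def test_identical_count_multisets_p_one(self):
        presence = {f"a{k}": {f"F{j}" for j in range(k)} for k in range(5)}
        presence.update({f"b{k}": {f"F{j}" for j in range(k)} for k in range(5)})
        _, p = count_comparison(
            presence, [f"a{k}" for k in range(5)], [f"b{k}" for k in range(5)]
        )
        assert p == pytest.approx(1.0)

    def test_disjoint_ranges_exact_p(self):
        presence = {f"a{k}": {f"F{j}" for j in range(k + 10)} for k in range(5)}
        presence.update({f"b{k}": {f"F{j}" for j in range(k)} for k in range(5)})
        counts, p = count_comparison(
            presence, [f"a{k}" for k in range(5)], [f"b{k}" for k in range(5)]
        )
        assert p == pytest.approx(2 / 252, rel=1e-6)
        assert counts["a0"] == 10

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(1)
        fams = [f"F{j}" for j in range(40)]
        presence = {}
        for k in range(30):
            presence[f"a{k}"] = {f for f in fams if rng.random() < 0.5}
            presence[f"b{k}"] = {f for f in fams if rng.random() < 0.25}
        _, p = count_comparison(
            presence, [f"a{k}" for k in range(30)], [f"b{k}" for k in range(30)]
        )
        assert p < 0.05
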