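"""Mixed-model association, resampling procedures, prevalence link, burden."""

import numpy as np
import pandas as pd
import pytest

from ecoresp.assoc import (
    _group_blocks,
    _reml_random_intercept,
    case_bootstrap_ci,
    cohens_d,
    exogenous_burden,
    fit_lmm,
    permutation_test_lmm,
    prevalence_association,
)
from ecoresp.core_io import (
    OguCountTable,
    OguMetadata,
    compute_prevalence,
    tss_normalize,
)
from ecoresp.diffrank import fit_differentials
from ecoresp.simulate import SimConfig, simulate_cohorts


def _grouped_data(seed, n_groups=8, n=25, beta=1.5, g_sd=1.0, e_sd=1.0):
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(n_groups)], n)
    x = (rng.random(n_groups * n) < 0.5).astype(float)
    a = np.repeat(rng.normal(0, g_sd, n_groups), n)
    y = 2.0 + beta * x + a + rng.normal(0, e_sd, n_groups * n)
    return y, x, groups


class TestFitLmm:
    def test_zero_group_variance_matches_ols(self):
        # residuals demeaned within groups: the REML group variance sits at
        # the boundary and the mixed fit collapses to ordinary regression
        rng = np.random.default_rng(0)
        groups = np.repeat([f"g{i}" for i in range(6)], 20)
        x = np.tile((np.arange(20) < 10).astype(float), 6)  # balanced per group
        e = rng.normal(0, 1, 120)
        for g in np.unique(groups):
            e[groups == g] -= e[groups == g].mean()
        y = 2.0 + 1.5 * x + e
        fit = fit_lmm(y, pd.DataFrame({"x": x}), groups)
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.fixed_effects["x"].estimate == pytest.approx(
            float(ols.params[1]), abs=1e-4
        )
        assert fit.random_intercept_variance < 1e-4

    def test_fast_reml_matches_mixedlm(self):
        import statsmodels.api as sm

        y, x, groups = _grouped_data(1, g_sd=1.0)
        X = np.column_stack([np.ones(y.size), x])
        fast = _reml_random_intercept(y, X, _group_blocks(groups))
        mixed = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        assert fast.beta[1] == pytest.approx(float(np.asarray(mixed.params)[1]),
                                             abs=1e-4)
        assert fast.sigma_e2 == pytest.approx(float(mixed.scale), rel=1e-3)

    def test_recovers_planted_beta(self):
        covered = 0
        for seed in range(20):
            y, x, groups = _grouped_data(seed, n_groups=10, n=30, beta=1.5)
            fit = fit_lmm(y, pd.DataFrame({"x": x}), groups)
            if 1.3 <= fit.fixed_effects["x"].estimate <= 1.7:
                covered += 1
        assert covered >= 17

    def test_r2_ordering_and_icc_range(self):
        y, x, groups = _grouped_data(2)
        fit = fit_lmm(y, pd.DataFrame({"x": x}), groups)
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1
        assert 0 <= fit.icc < 1

    def test_single_group_falls_back_to_ols(self):
        y, x, _ = _grouped_data(3, n_groups=1)
        fit = fit_lmm(y, pd.DataFrame({"x": x}), ["only"] * y.size)
        assert fit.fit_method == "ols_single_group_fallback"

    def test_null_p_roughly_uniform(self):
        ps = []
        for seed in range(40):
            y, x, groups = _grouped_data(100 + seed, n_groups=6, n=20, beta=0.0)
            fit = fit_lmm(y, pd.DataFrame({"x": x}), groups)
            ps.append(fit.fixed_effects["x"].p_value)
        assert 0.3 < np.mean(ps) < 0.7
        assert np.mean(np.asarray(ps) < 0.05) < 0.2


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3])[0] == pytest.approx(0.0)

    def test_unit_shift_limit(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1, 1, 4000)
        b = rng.normal(0, 1, 4000)
        d, lo, hi = cohens_d(a, b)
        assert d == pytest.approx(1.0, abs=0.08)
        assert lo < d < hi

    def test_equal_means_zero_by_hand(self):
        d, _, _ = cohens_d([0, 0, 2, 2], [1, 1, 1, 1])
        assert d == pytest.approx(0.0)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestCaseBootstrap:
    def test_deterministic_per_seed(self):
        y, x, groups = _grouped_data(4)
        kw = dict(n_boot=150, seed=9)
        ci1 = case_bootstrap_ci(y, pd.DataFrame({"x": x}), groups, **kw)
        ci2 = case_bootstrap_ci(y, pd.DataFrame({"x": x}), groups, **kw)
        assert ci1 == ci2

    def test_strong_effect_ci_excludes_zero(self):
        y, x, groups = _grouped_data(5, beta=2.0)
        ci = case_bootstrap_ci(y, pd.DataFrame({"x": x}), groups, n_boot=200, seed=1)
        lo, hi = ci["x"]
        assert lo > 0

    def test_null_ci_covers_zero(self):
        y, x, groups = _grouped_data(6, beta=0.0)
        ci = case_bootstrap_ci(y, pd.DataFrame({"x": x}), groups, n_boot=200, seed=1)
        lo, hi = ci["x"]
        assert lo < 0 < hi


class TestPermutationLmm:
    def test_strong_effect_minimal_p(self):
        y, x, groups = _grouped_data(7, beta=5.0, e_sd=1.0)
        p = permutation_test_lmm(y, x, None, groups, n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_deterministic_per_seed(self):
        y, x, groups = _grouped_data(8, beta=0.3)
        p1 = permutation_test_lmm(y, x, None, groups, n_perm=99, seed=5)
        p2 = permutation_test_lmm(y, x, None, groups, n_perm=99, seed=5)
        assert p1 == p2

    def test_null_p_not_extreme(self):
        ps = [
            permutation_test_lmm(*_grouped_data(200 + s, beta=0.0)[:2],
                                 None, _grouped_data(200 + s)[2],
                                 n_perm=99, seed=s)
            for s in range(10)
        ]
        assert 0.2 < np.mean(ps) < 0.8


@pytest.fixture(scope="module")
def linked():
    cfg = SimConfig(
        seed=2, n_datasets=4, samples_per_dataset=60, n_ogus=300,
        target_sparsity=0.4, prevalence_shape=(2.0, 2.0),
        baseline_log_sd=1.0, noise_log_sd=0.3,
        prevalence_effect_rho=0.3, frac_allochthonous=0.0,
    )
    table, smeta, ometa, truth = simulate_cohorts(cfg)
    diff = fit_differentials(table, smeta)
    profiles = compute_prevalence(table, smeta)
    return table, smeta, ometa, diff, profiles


class TestPrevalenceAssociation:
    def test_positive_link_recovered(self, linked):
        _, _, _, diff, profiles = linked
        res = prevalence_association(diff, profiles)
        assert res.rho > 0.1 and res.p_value < 1e-4
        assert res.mode == "per_pair"

    def test_mean_mode_and_completeness_covariate(self, linked):
        _, _, ometa, diff, profiles = linked
        comp = {o: m.completeness for o, m in ometa.items()}
        res = prevalence_association(diff, profiles, completeness_of=comp,
                                     mode="mean")
        assert "completeness" in res.covariates_removed
        assert res.rho > 0.1

    def test_threshold_curve_monotone_cutoffs(self, linked):
        _, _, _, diff, profiles = linked
        res = prevalence_association(diff, profiles, thresholds=(1, 5, 20, 50))
        cutoffs = [pt.cutoff for pt in res.threshold_curve]
        assert cutoffs == sorted(cutoffs)
        for pt in res.threshold_curve:
            if pt.stable:
                assert pt.rho > 0

    def test_dataset_relabeling_invariance(self, linked):
        table, smeta, _, diff, profiles = linked
        res1 = prevalence_association(diff, profiles)
        renamed = diff.coef.rename(
            columns={d: f"Z_{d}" for d in diff.coef.columns}
        )
        from ecoresp.diffrank import DifferentialTable

        diff2 = DifferentialTable(
            renamed, {f"Z_{d}": v for d, v in diff.converged.items()},
            {f"Z_{d}": v for d, v in diff.n_iter.items()}, diff.reg_strength,
        )
        res2 = prevalence_association(diff2, profiles)
        assert res1.rho == pytest.approx(res2.rho, abs=1e-10)

    def test_permutation_p_small_with_planted_link(self, linked):
        table, smeta, _, diff, profiles = linked
        res = prevalence_association(
            diff, profiles, n_perm=19, seed=0, counts=table, meta=smeta,
        )
        assert res.permutation_p == pytest.approx(1 / 20)


class TestExogenousBurden:
    @pytest.fixture
    def flagged(self):
        t = OguCountTable(
            ["s1", "s2"], ["a", "b", "c"],
            np.array([[0.10, 0.05, 0.85], [0.0, 0.2, 0.8]]), is_relative=True,
        )
        meta = {
            "a": OguMetadata("a", source_flags=frozenset({"oral"})),
            "b": OguMetadata("b", source_flags=frozenset({"food"})),
            "c": OguMetadata("c"),
        }
        return t, meta

    def test_sum_of_flagged(self, flagged):
        t, meta = flagged
        b = exogenous_burden(t, meta, ("oral", "food"))
        assert b["s1"] == pytest.approx(0.15)
        assert b["s2"] == pytest.approx(0.2)

    def test_no_flagged_gives_zero(self, flagged):
        t, meta = flagged
        b = exogenous_burden(t, meta, ("vagina",))
        assert (b == 0).all()

    def test_monotone_in_flag_set(self, flagged):
        t, meta = flagged
        b1 = exogenous_burden(t, meta, ("oral",))
        b2 = exogenous_burden(t, meta, ("oral", "food"))
        assert (b2 >= b1 - 1e-12).all()
        assert ((b2 >= 0) & (b2 <= 1)).all()

    def test_unknown_flag_rejected(self, flagged):
        t, meta = flagged
        with pytest.raises(ValueError, match="unknown"):
            exogenous_burden(t, meta, ("soil",))

    def test_raw_table_rejected(self, flagged):
        _, meta = flagged
        raw = OguCountTable(["s1"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="TSS"):
            exogenous_burden(raw, meta)

    def test_planted_nr_burden_detected_by_lmm(self):
        cfg = SimConfig(
            seed=4, n_datasets=6, samples_per_dataset=60, n_ogus=150,
            target_sparsity=0.5, prevalence_shape=(2.0, 2.0),
            baseline_log_sd=1.0, noise_log_sd=0.3,
            frac_allochthonous=0.15, allochthonous_nr_shift=1.5, effect_sd=0.3,
        )
        table, smeta, ometa, _ = simulate_cohorts(cfg)
        rel = tss_normalize(table)
        burden = exogenous_burden(rel, ometa)
        x = pd.DataFrame(
            {"response": [1.0 if smeta[s].response == "R" else 0.0
                          for s in rel.sample_ids]}
        )
        groups = [smeta[s].dataset_id for s in rel.sample_ids]
        fit = fit_lmm(np.log(burden.values + 1e-6), x, groups)
        fe = fit.fixed_effects["response"]
        assert fe.estimate < 0 and fe.p_value < 0.05
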