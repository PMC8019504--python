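import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crtlmm import (
    DesignConfig,
    NullDataset,
    anova_decompose,
    cluster_means_ttest,
    design_effect,
    design_effect_se_multiplier,
    df_between_within,
    df_residual,
    df_satterthwaite,
    fit_ml,
    fit_reml,
    generate_null_dataset,
    lrt,
    numeric_oracle_fit,
    replicate_rng,
    run_all_tests,
    wald_test,
)

from conftest import make_dataset


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("K, N, expected", [(10, 3, 28), (100, 50, 4998)])
    def test_residual(self, K, N, expected):
        assert df_residual(K, N) == expected

    @pytest.mark.parametrize("K, expected", [(10, 8), (20, 18), (100, 98)])
    def test_between_within(self, K, expected):
        assert df_between_within(K) == expected

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            df_between_within(2)
        with pytest.raises(ValueError):
            df_residual(1, 2)

    def test_t_converges_to_z_at_large_df(self):
        # residual-DF p-values approach normal p-values once K*N >= 5000
        df = df_residual(100, 50)
        for t_star in np.linspace(-4, 4, 33):
            p_t = 2 * stats.t.sf(abs(t_star), df)
            p_z = 2 * stats.norm.sf(abs(t_star))
            assert abs(p_t - p_z) < 1e-4


class TestSatterthwaite:
    def test_interior_equals_between_within(self):
        data = make_dataset(K=20, N=50, sigma_b2=0.5, seed=1)
        fit = fit_reml(data)
        assert not fit.boundary
        assert df_satterthwaite(fit, 20, 50) == pytest.approx(18.0, abs=1e-6)

    def test_boundary_equals_residual(self):
        # force a boundary fit: equal cluster means, within-cluster spread
        data = NullDataset(
            y=np.tile([-1.0, 0.0, 1.0], 10),
            cluster=np.repeat(np.arange(1, 11), 3),
            arm=np.repeat([0] * 5 + [1] * 5, 3),
        )
        fit = fit_reml(data)
        assert fit.boundary
        assert df_satterthwaite(fit, 10, 3) == pytest.approx(28.0, abs=1e-6)

    def test_bounded_by_bw_and_residual(self, random_fixtures):
        for data in random_fixtures:
            K, N = data.K, data.N
            fit = fit_reml(data, validate=False)
            df = df_satterthwaite(fit, K, N)
            assert df_between_within(K) - 1e-9 <= df <= df_residual(K, N) + 1e-9

    def test_rejects_invalid_fits(self):
        data = make_dataset(seed=2)
        with pytest.raises(ValueError):
            df_satterthwaite(fit_ml(data), data.K, data.N)
        with pytest.raises(ValueError):
            df_satterthwaite(fit_ml(data, include_treatment=False), data.K, data.N)


class TestWald:
    def test_zero_statistic_gives_p_one(self):
        data = make_dataset(K=6, N=3, seed=3)
        # symmetrize so the arm means coincide: beta1_hat = 0
        y = data.y.reshape(6, 3)
        y[3:] = y[:3]
        sym = NullDataset(y=y.ravel(), cluster=data.cluster, arm=data.arm)
        fit = fit_reml(sym)
        for m in ("wald_residual", "wald_between_within", "wald_satterthwaite", "wald_z"):
            res = wald_test(fit, m, 6, 3)
            assert res.statistic == pytest.approx(0.0, abs=1e-12)
            assert res.p_value == pytest.approx(1.0)

    def test_z_reference_quantile(self, hand_dataset):
        # 1.96 is the familiar two-sided 5% normal quantile
        assert 2 * stats.norm.sf(1.96) == pytest.approx(0.05, abs=1e-4)
        res = wald_test(fit_reml(hand_dataset), "wald_z", 4, 2)
        assert res.df == math.inf

    def test_p_value_ordering_across_df_choices(self, random_fixtures):
        """t CDF is monotone in DF: p_bw >= p_satt >= p_resid >= p_z at fixed t*."""
        for data in random_fixtures[:40]:
            fit = fit_reml(data, validate=False)
            if abs(fit.t_statistic) < 1e-12:
                continue
            K, N = data.K, data.N
            p = {m: wald_test(fit, m, K, N).p_value
                 for m in ("wald_between_within", "wald_satterthwaite", "wald_residual", "wald_z")}
            assert p["wald_between_within"] >= p["wald_satterthwaite"] - 1e-12
            assert p["wald_satterthwaite"] >= p["wald_residual"] - 1e-12
            assert p["wald_residual"] >= p["wald_z"] - 1e-12

    def test_kenward_roger_aliases_satterthwaite(self, hand_dataset):
        fit = fit_reml(hand_dataset)
        kr = wald_test(fit, "wald_kenward_roger", 4, 2)
        sat = wald_test(fit, "wald_satterthwaite", 4, 2)
        assert kr.df == sat.df and kr.p_value == sat.p_value

    def test_unknown_method_rejected(self, hand_dataset):
        with pytest.raises(ValueError):
            wald_test(fit_reml(hand_dataset), "wald_container", 4, 2)

    def test_requires_full_model(self, hand_dataset):
        with pytest.raises(ValueError):
            wald_test(fit_ml(hand_dataset, include_treatment=False), "wald_z", 4, 2)


class TestLRT:
    def test_equal_logliks(self, hand_dataset):
        null = fit_ml(hand_dataset, include_treatment=False)
        full = fit_ml(hand_dataset, include_treatment=True)
        fake_full = type(full)(**{**full.__dict__, "loglik": null.loglik})
        res = lrt(null, fake_full)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_quantile(self, hand_dataset):
        null = fit_ml(hand_dataset, include_treatment=False)
        full = fit_ml(hand_dataset, include_treatment=True)
        shifted = type(full)(**{**full.__dict__, "loglik": null.loglik + 3.84 / 2})
        assert lrt(null, shifted).p_value == pytest.approx(0.05, abs=3e-4)

    def test_matches_numeric_oracle(self, hand_dataset):
        null, full = fit_ml(hand_dataset, False), fit_ml(hand_dataset, True)
        o_null = numeric_oracle_fit(hand_dataset, "ML", include_treatment=False)
        o_full = numeric_oracle_fit(hand_dataset, "ML", include_treatment=True)
        assert lrt(null, full).statistic == pytest.approx(
            lrt(o_null, o_full).statistic, abs=1e-7
        )

    def test_rejects_reml_fits(self, hand_dataset):
        null = fit_ml(hand_dataset, include_treatment=False)
        with pytest.raises(ValueError, match="REML"):
            lrt(null, fit_reml(hand_dataset))

    def test_rejects_swapped_arguments(self, hand_dataset):
        null, full = fit_ml(hand_dataset, False), fit_ml(hand_dataset, True)
        with pytest.raises(ValueError):
            lrt(full, null)

    def test_clamps_negative_statistic(self, hand_dataset):
        null, full = fit_ml(hand_dataset, False), fit_ml(hand_dataset, True)
        barely_lower = type(full)(**{**full.__dict__, "loglik": null.loglik - 1e-12})
        res = lrt(null, barely_lower)
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestClusterMeansTTest:
    def test_hand_fixture(self, hand_dataset):
        # cluster means (1,3) vs (2,4): diff 1, pooled var 2, t = 1/sqrt(2), DF 2
        res = cluster_means_ttest(hand_dataset)
        assert res.statistic == pytest.approx(1 / math.sqrt(2))
        assert res.df == 2.0
        assert res.p_value == pytest.approx(0.5527864045, abs=1e-9)

    def test_all_means_equal(self):
        data = NullDataset(
            y=np.tile([-1.0, 1.0], 4), cluster=np.repeat([1, 2, 3, 4], 2),
            arm=np.repeat([0, 0, 1, 1], 2),
        )
        assert cluster_means_ttest(data).p_value == pytest.approx(1.0)

    def test_equals_msb_only_wald_statistic(self, random_fixtures):
        """t* = beta1_hat / sqrt(4*MSB/(K*N)) — the between-within Wald form."""
        for data in random_fixtures[:50]:
            d = anova_decompose(data, validate=False)
            expected = (d.mean_trt - d.mean_ctrl) / math.sqrt(4 * d.msb / (d.K * d.N))
            res = cluster_means_ttest(data, validate=False)
            assert res.statistic == pytest.approx(expected, rel=1e-10)
            fit = fit_reml(data, validate=False)
            if not fit.boundary:
                # interior REML: sigma2 + N*sigma_b2 = MSB exactly, so the
                # between-within Wald statistic coincides with the t-test
                bw = wald_test(fit, "wald_between_within", d.K, d.N)
                assert bw.statistic == pytest.approx(res.statistic, rel=1e-10)


class TestScaleInvariance:
    @pytest.mark.parametrize("c", [0.1, 10.0])
    def test_all_tests_invariant_to_outcome_scale(self, c):
        data = make_dataset(K=10, N=5, sigma_b2=0.3, seed=6)
        scaled = NullDataset(y=c * data.y, cluster=data.cluster, arm=data.arm)

        def battery(d):
            return run_all_tests(d, fit_reml(d), fit_ml(d, False), fit_ml(d, True))

        for m, a in battery(data).items():
            b = battery(scaled)[m]
            assert a.df == pytest.approx(b.df, rel=1e-12)
            assert a.statistic == pytest.approx(b.statistic, rel=1e-10)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-10)

    @pytest.mark.parametrize("c", [0.25, 4.0])
    def test_bitwise_invariance_under_power_of_two_scaling(self, c):
        # multiplication by a power of two is exact in IEEE arithmetic and
        # commutes with every rounding, so the Wald family and the t-test
        # are invariant to the bit; the LRT's log-likelihood log terms do
        # not commute with exact scaling, leaving it invariant only to
        # machine rounding
        data = make_dataset(K=10, N=5, sigma_b2=0.3, seed=6)
        scaled = NullDataset(y=c * data.y, cluster=data.cluster, arm=data.arm)

        def battery(d):
            return run_all_tests(d, fit_reml(d), fit_ml(d, False), fit_ml(d, True))

        for m, a in battery(data).items():
            b = battery(scaled)[m]
            if m == "lrt":
                assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
            else:
                assert (a.statistic, a.df, a.p_value) == (b.statistic, b.df, b.p_value)


class TestPValueUniformity:
    def test_cluster_means_p_uniform_under_null(self):
        """The cluster-means t reference is exact, so null p-values are U(0,1)."""
        cfg = DesignConfig(K=10, N=5, sigma_b2=0.2, sigma2=1.0)
        pvals = [
            cluster_means_ttest(
                generate_null_dataset(cfg, rng=replicate_rng(3, 0, r)), validate=False
            ).p_value
            for r in range(2000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_between_within_p_uniform_at_large_icc(self):
        # at large ICC boundary truncation never triggers and the
        # between-within reference is exact
        cfg = DesignConfig(K=20, N=10, sigma_b2=5.0, sigma2=1.0)
        pvals = []
        for r in range(2000):
            data = generate_null_dataset(cfg, rng=replicate_rng(4, 0, r))
            fit = fit_reml(data, validate=False)
            pvals.append(wald_test(fit, "wald_between_within", 20, 10).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestDesignEffect:
    def test_reference_values(self):
        assert design_effect(10, 0.01) == pytest.approx(1.09)
        assert design_effect(1000, 0.01) == pytest.approx(10.99)
        assert design_effect_se_multiplier(1000, 0.01) == pytest.approx(3.315, abs=5e-4)

    @given(rho=st.floats(0, 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_single_subject_clusters_have_no_effect(self, rho):
        assert design_effect(1, rho) == 1.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            design_effect(0, 0.5)
        with pytest.raises(ValueError):
            design_effect(10, 1.5)
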