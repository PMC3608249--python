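import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famewas.pedigree import kinship_matrix
from famewas.varcomp import (
    PolygenicModel,
    association_test,
    back_transform_effect,
    covariate_design,
    covariate_scan,
    fit_polygenic,
    heritability_test,
    normalize_expression,
    rank_normalize,
)
from famewas.simulate import simulate_trait_with_h2

from _oracles import gls_beta


class TestRankNormalize:
    def test_three_values(self):
        z = rank_normalize([5.0, 1.0, 9.0])
        assert z == pytest.approx([0.0, -0.9674, 0.9674], abs=1e-4)

    def test_monotone_invariance(self, rng):
        x = rng.normal(size=50)
        assert np.allclose(rank_normalize(x), rank_normalize(np.exp(3 * x)))

    def test_ties_share_value(self):
        z = rank_normalize([1.0, 1.0, 2.0])
        assert z[0] == z[1]

    def test_missing_propagates(self):
        z = rank_normalize([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(z[1]) and not np.isnan(z[0])

    def test_mean_near_zero(self, rng):
        z = rank_normalize(rng.normal(size=200))
        assert abs(z.mean()) < 1e-8

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_normalize([2.0, 2.0, 2.0])


class TestPolygenicFit:
    def test_h2_zero_matches_ols_loglik(self, small_multi_family, rng):
        K = kinship_matrix(small_multi_family)
        n = len(K.ids)
        X = covariate_design(rng.uniform(20, 60, n), rng.integers(0, 2, n).astype(bool))
        y = rng.normal(size=n)
        fit = PolygenicModel(K).fit(y, X, h2_fixed=0.0)
        import statsmodels.api as sm

        ols = sm.OLS(y, np.asarray(X)).fit()
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-6)
        assert fit.beta == pytest.approx(ols.params, abs=1e-8)

    def test_unrelated_cohort_completes_at_boundary(self, rng):
        n = 60
        phi = np.eye(n) * 0.5
        X = pd.DataFrame({"intercept": np.ones(n)})
        y = rng.normal(size=n)
        fit = fit_polygenic(y, X, phi)
        assert 0.0 <= fit.h2 <= 1.0
        assert np.isfinite(fit.loglik)

    def test_gls_oracle_small_instance(self, small_multi_family, rng):
        """At a fixed variance ratio the fit equals explicit-inverse GLS."""
        K = kinship_matrix(small_multi_family)
        n = len(K.ids)
        s2a, s2e = 0.6, 0.4
        omega = 2 * K.phi * s2a + np.eye(n) * s2e
        X = pd.DataFrame(
            {"intercept": np.ones(n), "x": rng.normal(size=n)}
        )
        y = rng.multivariate_normal(np.zeros(n), omega)
        fit = PolygenicModel(K).fit(y, X, h2_fixed=s2a / (s2a + s2e))
        beta_oracle = gls_beta(y, np.asarray(X), omega)
        assert fit.beta == pytest.approx(beta_oracle, abs=1e-8)

    def test_nested_model_likelihood_monotone(self, small_multi_family, rng):
        K = kinship_matrix(small_multi_family)
        n = len(K.ids)
        model = PolygenicModel(K)
        X = covariate_design(rng.uniform(20, 60, n), rng.integers(0, 2, n).astype(bool))
        y = rng.normal(size=n)
        full = model.fit(y, X)
        dropped = model.fit(y, X.drop(columns=["age"]))
        assert full.loglik >= dropped.loglik - 1e-8

    def test_h2_recovery_on_families(self, rng):
        """Moderate-size recovery: mean estimate near generative h2."""
        from famewas.simulate import default_config, gen_pedigrees

        cfg = default_config(n_families=25)
        h2_true = 0.5
        ests = []
        for seed in range(12):
            ped = gen_pedigrees(cfg, seed=seed)
            K = kinship_matrix(ped)
            y = simulate_trait_with_h2(K, h2_true, 0.0, 1.0, seed=seed + 100)
            X = pd.DataFrame({"intercept": np.ones(len(y))})
            ests.append(PolygenicModel(K).fit(y, X).h2)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - h2_true) <= max(3 * se, 0.05)

    def test_singular_design_rejected(self, small_multi_family, rng):
        K = kinship_matrix(small_multi_family)
        n = len(K.ids)
        X = pd.DataFrame({"a": np.ones(n), "b": np.ones(n)})
        with pytest.raises(ValueError, match="singular"):
            PolygenicModel(K).fit(rng.normal(size=n), X)


class TestHeritabilityTest:
    def test_mixture_null_at_chi2_5pct_point(self):
        """T at the chi2_1 5% point halves to p = 0.025."""
        fit_full = _dummy_fit(loglik=0.0 + 3.8415 / 2)
        fit_h0 = _dummy_fit(loglik=0.0)
        assert heritability_test(fit_full, fit_h0) == pytest.approx(0.025, abs=2e-4)

    def test_zero_statistic_p_one(self):
        assert heritability_test(_dummy_fit(0.0), _dummy_fit(0.0)) == 1.0

    def test_mismatched_designs_rejected(self):
        with pytest.raises(ValueError):
            heritability_test(_dummy_fit(1.0, cols=["a"]), _dummy_fit(0.0, cols=["b"]))


def _dummy_fit(loglik, cols=("intercept",)):
    from famewas.varcomp import VarCompFit

    return VarCompFit(
        sigma2_a=0.0, sigma2_e=1.0, h2=0.0, h2_se=float("nan"),
        beta=np.zeros(len(cols)), beta_se=np.zeros(len(cols)),
        loglik=loglik, n=10, columns=list(cols),
    )


class TestAssociation:
    def test_regression_recovery_no_genetics(self, rng):
        n = 400
        phi = np.eye(n) * 0.5
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n) * np.sqrt(1 - 0.25)
        X = pd.DataFrame({"intercept": np.ones(n)})
        res = association_test(y, X, phi, x, rank_normalize_focal=False)
        assert abs(res.beta - 0.5) <= 3 * res.se
        assert res.p_value < 1e-6
        assert res.variance_explained == pytest.approx(
            res.beta**2 * np.var(x) / np.var(y), rel=1e-10
        )

    def test_null_rejection_rate(self, small_multi_family, rng):
        K = kinship_matrix(small_multi_family)
        model = PolygenicModel(K)
        n = len(K.ids)
        X = pd.DataFrame({"intercept": np.ones(n)})
        rejections = 0
        reps = 300
        for _ in range(reps):
            y = simulate_trait_with_h2(K, 0.3, 0.0, 1.0, rng)
            x = rng.normal(size=n)
            res = association_test(y, X, model, x, rank_normalize_focal=False)
            rejections += res.p_value < 0.05
        rate = rejections / reps
        ci = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= ci

    def test_constant_focal_rejected(self, small_multi_family):
        K = kinship_matrix(small_multi_family)
        n = len(K.ids)
        X = pd.DataFrame({"intercept": np.ones(n)})
        with pytest.raises(ValueError, match="constant"):
            association_test(np.random.default_rng(0).normal(size=n), X, K, np.ones(n))


class TestCovariateScan:
    def test_positive_age_slope_recovered(self, rng):
        from famewas.simulate import default_config, gen_pedigrees

        cfg = default_config(n_families=20)
        signs = []
        for seed in range(8):
            ped = gen_pedigrees(cfg, seed=seed)
            K = kinship_matrix(ped)
            n = len(K.ids)
            age = rng.uniform(18, 75, n)
            fem = rng.integers(0, 2, n).astype(bool)
            meth = 0.2 + 4e-4 * (age - age.mean()) + rng.normal(0, 0.02, n)
            X = covariate_design(age, fem)
            res = covariate_scan(np.clip(meth, 0, 1), X, K)
            signs.append(res["beta_age"] > 0)
            assert res["p_age"] < 0.05
        assert all(signs)

    def test_raw_scale_beta_magnitude(self, rng):
        """beta_age is reported per year on the fraction scale."""
        from famewas.simulate import default_config, gen_pedigrees

        ped = gen_pedigrees(default_config(n_families=30), seed=1)
        K = kinship_matrix(ped)
        n = len(K.ids)
        age = rng.uniform(18, 75, n)
        fem = rng.integers(0, 2, n).astype(bool)
        slope = 5e-4
        meth = 0.3 + slope * (age - age.mean()) + rng.normal(0, 0.01, n)
        res = covariate_scan(meth, covariate_design(age, fem), K)
        assert res["beta_age"] == pytest.approx(slope, rel=0.35)


class TestBackTransform:
    def test_zero_beta(self):
        assert back_transform_effect(0.0, 10.0, 0.05) == 0.0

    def test_unit_conversion_identity(self):
        assert back_transform_effect(1.0, 10.0, 0.01) == pytest.approx(10.0)

    def test_doubling_meth_sd_halves_effect(self):
        a = back_transform_effect(0.2, 40.0, 0.02)
        b = back_transform_effect(0.2, 40.0, 0.04)
        assert a == pytest.approx(2 * b)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            back_transform_effect(0.1, 0.0, 0.02)


class TestNormalizeExpression:
    def test_identical_sorted_intensities_identical_output(self):
        df = pd.DataFrame([[1.0, 2.0, 4.0], [4.0, 1.0, 2.0]], index=["a", "b"])
        out = normalize_expression(df)
        assert sorted(out.loc["a"]) == sorted(out.loc["b"])

    def test_shared_value_multiset(self, rng):
        df = pd.DataFrame(rng.lognormal(3, 1, size=(5, 20)))
        out = normalize_expression(df)
        ref = np.sort(out.iloc[0].to_numpy())
        for i in range(1, 5):
            assert np.allclose(np.sort(out.iloc[i].to_numpy()), ref)

    def test_order_preserved_within_sample(self, rng):
        df = pd.DataFrame(rng.lognormal(3, 1, size=(4, 15)))
        out = normalize_expression(df)
        for i in range(4):
            raw_order = np.argsort(df.iloc[i].to_numpy())
            norm_sorted = out.iloc[i].to_numpy()[raw_order]
            assert np.all(np.diff(norm_sorted) >= -1e-12)

    def test_non_positive_intensity_named(self):
        df = pd.DataFrame([[1.0, 0.0]], index=["s1"], columns=["p1", "p2"])
        with pytest.raises(ValueError, match="p2"):
            normalize_expression(df)
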