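"""The interaction scan: least-squares oracle equivalence, sandwich
covariance against dense-matrix and statsmodels oracles, test invariances,
and null calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gweiskit.design import DesignMatrix, build_design
from gweiskit.formats import MISSING, GenotypeMatrix
from gweiskit.gweis import (
    fit_ols,
    interaction_scan,
    interaction_test,
    joint_test,
    run_gweis,
    sandwich_covariance,
)
from gweiskit.simulate import (
    EnvironmentVector,
    SimConfig,
    simulate_environment,
    simulate_genotypes,
    simulate_phenotype,
)


def _design_from(matrix, names=None):
    matrix = np.asarray(matrix, dtype=float)
    names = names or [f"x{i}" for i in range(matrix.shape[1])]
    return DesignMatrix(
        matrix, {"all": np.arange(matrix.shape[1])}, np.arange(matrix.shape[0]), names
    )


class TestFitOLS:
    def test_matches_pseudoinverse_oracle(self, rng):
        X = _design_from(rng.normal(size=(50, 5)))
        y = rng.normal(size=50)
        fit = fit_ols(y, X)
        oracle = np.linalg.pinv(X.matrix) @ y
        np.testing.assert_allclose(fit.beta, oracle, rtol=1e-10)

    def test_intercept_only_closed_form(self, rng):
        y = rng.normal(loc=3.0, size=40)
        X = _design_from(np.ones((40, 1)))
        fit = fit_ols(y, X)
        assert fit.beta[0] == pytest.approx(y.mean(), rel=1e-12)
        assert np.sqrt(fit.model_cov[0, 0]) == pytest.approx(
            y.std(ddof=1) / np.sqrt(40), rel=1e-12
        )

    def test_perfect_fit_zero_residuals_and_covariance(self, rng):
        A = rng.normal(size=(30, 3))
        y = A @ np.array([1.0, -2.0, 0.5])
        fit = fit_ols(y, _design_from(A))
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.model_cov, 0.0, atol=1e-18)

    def test_residuals_orthogonal_to_design(self, rng):
        A = rng.normal(size=(80, 6))
        y = rng.normal(size=80)
        fit = fit_ols(y, _design_from(A))
        As = A / np.linalg.norm(A, axis=0)
        assert np.abs(As.T @ fit.residuals).max() / 80 < 1e-8

    def test_underdetermined_rejected(self, rng):
        A = rng.normal(size=(4, 5))
        with pytest.raises(ValueError, match="exceed"):
            fit_ols(rng.normal(size=4), _design_from(A))


class TestSandwich:
    def test_equal_magnitude_residuals_hc1_equals_model(self, rng):
        A = rng.normal(size=(40, 4))
        X = _design_from(A)
        fit = fit_ols(rng.normal(size=40), X)
        s = np.sqrt((fit.residuals**2).mean())
        resid = s * np.sign(rng.normal(size=40))
        hc1 = sandwich_covariance(X, resid, "HC1")
        n, p = A.shape
        model = (resid @ resid) / (n - p) * np.linalg.inv(A.T @ A)
        np.testing.assert_allclose(hc1, model, rtol=1e-12)

    @pytest.mark.parametrize("flavor,c_fn", [("HC0", lambda n, p: 1.0), ("HC1", lambda n, p: n / (n - p))])
    def test_matches_dense_triple_product_oracle(self, rng, flavor, c_fn):
        n, p = 60, 7
        A = rng.normal(size=(n, p))
        e = rng.normal(size=n)
        V = sandwich_covariance(_design_from(A), e, flavor)
        bread = np.linalg.inv(A.T @ A)
        oracle = bread @ A.T @ np.diag(c_fn(n, p) * e**2) @ A @ bread
        np.testing.assert_allclose(V, oracle, rtol=1e-12)

    @pytest.mark.parametrize("flavor", ["HC0", "HC1", "HC2", "HC3"])
    def test_matches_statsmodels(self, rng, flavor):
        import statsmodels.api as sm

        A = np.column_stack([np.ones(70), rng.normal(size=(70, 4))])
        y = rng.normal(size=70)
        X = _design_from(A)
        fit = fit_ols(y, X, robust_flavor=flavor)
        theirs = getattr(sm.OLS(y, A).fit(), f"cov_{flavor}")
        np.testing.assert_allclose(fit.robust_cov, theirs, rtol=1e-10, atol=1e-14)

    def test_psd_with_zero_residual_at_high_leverage(self, rng):
        A = np.column_stack([np.ones(30), rng.normal(size=30)])
        A[0, 1] = 25.0  # extreme leverage point
        e = rng.normal(size=30)
        e[0] = 0.0
        for flavor in ("HC0", "HC1", "HC2", "HC3"):
            V = sandwich_covariance(_design_from(A), e, flavor)
            assert np.linalg.eigvalsh(V).min() > -1e-12

    def test_dimension_mismatch_rejected(self, rng):
        X = _design_from(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError, match="does not match"):
            sandwich_covariance(X, rng.normal(size=19))


class TestInteractionAndJointTests:
    def _fit(self, rng, n=300, beta_gxe=0.0, beta_g=0.0, flavor="BM"):
        g = rng.binomial(2, 0.3, n).astype(float)
        e = rng.normal(size=n)
        y = beta_g * g + beta_gxe * g * e + rng.normal(size=n)
        X = build_design(g, EnvironmentVector(e, "continuous"), None, y=y)
        return fit_ols(y, X, robust_flavor=flavor)

    def test_single_column_wald_equals_t_squared(self, rng):
        fit = self._fit(rng, beta_gxe=0.4, flavor="HC1")
        t, df1, _ = interaction_test(fit, "robust")
        J = fit.design.group("snp_env")
        b = fit.beta[J]
        w = float(b @ np.linalg.solve(fit.robust_cov[np.ix_(J, J)], b))
        assert df1 == 1
        assert w == pytest.approx(t**2, rel=1e-10)

    def test_zero_coefficient_gives_p_one(self):
        n = 40
        g = np.tile([0.0, 1, 2, 1], 10)
        e = np.tile([-1.0, 0, 1, 0.5], 10)
        X = build_design(g, EnvironmentVector(e, "continuous"), None)
        fit = fit_ols(np.zeros(n), X)
        _, _, p = interaction_test(fit, "robust")
        assert p == 1.0

    def test_joint_test_beats_interaction_on_pure_main_effects(self, rng):
        hits_joint = hits_inter = 0
        for _ in range(40):
            fit = self._fit(rng, n=250, beta_g=0.25)
            hits_joint += joint_test(fit, "robust")[2] < 0.05
            hits_inter += interaction_test(fit, "robust")[2] < 0.05
        assert hits_joint > hits_inter

    def test_joint_test_requires_main_effect_column(self, rng):
        fit = self._fit(rng)
        fit.design.term_groups["snp"] = np.array([], dtype=int)
        with pytest.raises(ValueError, match="snp"):
            joint_test(fit, "robust")

    def test_joint_null_p_uniform(self, rng):
        cfg = SimConfig(n_samples=500, n_snps=800, ld_decay=0.0, sigma0=1.0, seed=88)
        G = simulate_genotypes(cfg)
        env = simulate_environment(cfg, "continuous")
        y = simulate_phenotype(G, env, None, cfg)
        res = interaction_scan(G, env, None, y, test="joint")
        assert stats.kstest(res["p_robust"], "uniform").pvalue > 0.01


class TestScan:
    def _cohort(self, seed=21, n=300, m=40, missing=0.02, **kw):
        cfg = SimConfig(n_samples=n, n_snps=m, ld_decay=0.2, sigma0=1.0,
                        missing_rate=missing, seed=seed, **kw)
        G = simulate_genotypes(cfg)
        env = simulate_environment(cfg, "continuous")
        rng = np.random.default_rng(seed)
        y = simulate_phenotype(G, env, None, cfg, rng=rng)
        return cfg, G, env, y

    def test_fast_path_matches_naive_per_snp_solver(self):
        cfg, G, env, y = self._cohort()
        res = interaction_scan(G, env, None, y)
        for j in range(G.n_snps):
            X = build_design(G.genotypes[:, j], env, None, y=y)
            fit = fit_ols(y[X.rows_used], X)
            t, _, p = interaction_test(fit, "robust")
            tm, _, pm = interaction_test(fit, "model")
            assert res["stat_robust"][j] == pytest.approx(t, rel=1e-8)
            assert res["p_robust"][j] == pytest.approx(p, rel=1e-8)
            assert res["p_model"][j] == pytest.approx(pm, rel=1e-8)
            assert res["beta"][j] == pytest.approx(fit.coef("snp_env")[0], rel=1e-8)

    def test_allele_flip_flips_beta_keeps_p(self):
        cfg, G, env, y = self._cohort(missing=0.0)
        res = interaction_scan(G, env, None, y)
        flipped = G.genotypes.copy()
        flipped = (2 - flipped).astype(np.int8)
        Gf = GenotypeMatrix(flipped, G.samples, G.markers.copy())
        res_f = interaction_scan(Gf, env, None, y)
        np.testing.assert_allclose(res_f["beta"], -res["beta"], rtol=1e-8)
        np.testing.assert_allclose(res_f["p_robust"], res["p_robust"], rtol=1e-10)

    def test_joint_sample_permutation_invariance(self, rng):
        cfg, G, env, y = self._cohort()
        perm = rng.permutation(G.n_samples)
        Gp = GenotypeMatrix(G.genotypes[perm], [G.samples[i] for i in perm], G.markers.copy())
        envp = EnvironmentVector(env.values[perm], "continuous")
        res = interaction_scan(G, env, None, y)
        resp = interaction_scan(Gp, envp, None, y[perm])
        np.testing.assert_allclose(resp["p_robust"], res["p_robust"], rtol=1e-9)

    def test_noise_free_causal_snp_attains_minimum_p(self):
        cfg = SimConfig(n_samples=200, n_snps=60, ld_decay=0.0, sigma0=1e-6,
                        beta_gxe=1.0, seed=31)
        G = simulate_genotypes(cfg)
        env = simulate_environment(cfg, "continuous")
        y = simulate_phenotype(G, env, None, cfg, causal_snps=[17])
        res = interaction_scan(G, env, None, y)
        assert int(np.nanargmin(res["p_robust"])) == 17

    def test_monomorphic_snps_skipped_with_reason(self):
        cfg, G, env, y = self._cohort(missing=0.0, m=10)
        geno = G.genotypes.copy()
        geno[:, 3] = 1  # constant
        Gm = GenotypeMatrix(geno, G.samples, G.markers.copy())
        res = interaction_scan(Gm, env, None, y)
        assert res["status"][3] == "monomorphic"
        assert np.isnan(res["p_robust"][3])

    def test_majority_skipped_escalates_to_error(self):
        cfg, G, env, y = self._cohort(missing=0.0, m=10)
        geno = G.genotypes.copy()
        geno[:, :6] = 0
        Gm = GenotypeMatrix(geno, G.samples, G.markers.copy())
        with pytest.raises(RuntimeError, match="misaligned"):
            interaction_scan(Gm, env, None, y)

    def test_homoskedastic_null_p_uniform_and_flavors_agree_at_large_n(self):
        cfg = SimConfig(n_samples=4000, n_snps=300, ld_decay=0.0, sigma0=1.0, seed=41)
        G = simulate_genotypes(cfg)
        env = simulate_environment(cfg, "continuous")
        y = simulate_phenotype(G, env, None, cfg)
        res = interaction_scan(G, env, None, y)
        assert stats.kstest(res["p_robust"], "uniform").pvalue > 0.01
        rel = np.abs(res["p_robust"] - res["p_model"]) / res["p_model"]
        assert np.quantile(rel, 0.95) < 0.10

    def test_heteroskedastic_null_model_chi2_exceeds_robust(self):
        cfg = SimConfig(n_samples=800, n_snps=400, ld_decay=0.0, sigma0=1.0,
                        hetero_delta=0.8, seed=51)
        G = simulate_genotypes(cfg)
        env = simulate_environment(cfg, "continuous")
        y = simulate_phenotype(G, env, None, cfg)
        res = interaction_scan(G, env, None, y)
        chi_m = np.median(res["stat_model"] ** 2)
        chi_r = np.median(res["stat_robust"] ** 2)
        assert chi_m > chi_r

    def test_categorical_environment_multi_df_test(self):
        cfg = SimConfig(n_samples=600, n_snps=25, ld_decay=0.0, sigma0=1.0, seed=61)
        G = simulate_genotypes(cfg)
        farms = simulate_environment(cfg, "categorical")
        rng = np.random.default_rng(61)
        y = simulate_phenotype(G, farms, None, cfg, rng=rng)
        table = run_gweis(G, farms, None, y)
        assert (table.loc[table["STATUS"] == "ok", "DF"] == 6).all()
        assert table["P_ROBUST"].between(0, 1).all()

    def test_summary_schema(self):
        cfg, G, env, y = self._cohort(m=12)
        table = run_gweis(G, env, None, y)
        for col in ("SNP", "CHR", "BP", "A1", "FREQ", "N", "BETA", "SE", "SE_ROBUST", "P", "P_ROBUST"):
            assert col in table.columns
        ok = table["STATUS"] == "ok"
        assert table.loc[ok, "FREQ"].between(0, 1).all()
        assert (table.loc[ok, "N"] <= G.n_samples).all()
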