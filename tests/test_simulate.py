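"""Generator behavior: marginal frequencies, LD structure, environment
series, phenotype model, and seed determinism."""

import numpy as np
import pytest

from gweiskit.design import build_design
from gweiskit.formats import MISSING
from gweiskit.gweis import fit_ols
from gweiskit.ld import ld_r2
from gweiskit.simulate import (
    ConfigurationError,
    EnvironmentVector,
    SimConfig,
    simulate_environment,
    simulate_genotypes,
    simulate_phenotype,
    simulate_trios,
)


def test_allele_frequency_matches_target_within_sampling_error():
    cfg = SimConfig(n_samples=10_000, n_snps=1, maf_range=(0.3, 0.3), ld_decay=0.0, seed=1)
    G = simulate_genotypes(cfg)
    freq = G.allele_freq()[0]
    se = np.sqrt(0.3 * 0.7 / (2 * cfg.n_samples))
    assert abs(freq - 0.3) < 3 * se


def test_no_ld_adjacent_r2_matches_independent_oracle(rng):
    n, pairs = 2000, 200
    cfg = SimConfig(n_samples=n, n_snps=pairs + 1, ld_decay=0.0, seed=2)
    G = simulate_genotypes(cfg)
    r2 = np.array([ld_r2(G, j, j + 1) for j in range(pairs)])
    # oracle: r2 between independently drawn genotype columns
    oracle = []
    for _ in range(pairs):
        p1, p2 = rng.uniform(0.05, 0.5, 2)
        a = rng.binomial(2, p1, n)
        b = rng.binomial(2, p2, n)
        oracle.append(np.corrcoef(a, b)[0, 1] ** 2)
    oracle = np.asarray(oracle)
    se = np.sqrt(oracle.var() / pairs + r2.var() / pairs)
    assert abs(r2.mean() - oracle.mean()) < 3 * se


def test_ld_decay_induces_adjacent_correlation():
    cfg = SimConfig(n_samples=2000, n_snps=101, ld_decay=0.8, seed=3)
    G = simulate_genotypes(cfg)
    r2 = np.array([ld_r2(G, j, j + 1) for j in range(100)])
    assert r2.mean() > 0.2


def test_zero_snps_gives_empty_panel_with_valid_map():
    cfg = SimConfig(n_samples=10, n_snps=0, seed=4)
    G = simulate_genotypes(cfg)
    assert G.genotypes.shape == (10, 0)
    assert len(G.markers) == 0


def test_marker_positions_strictly_increasing_per_chromosome():
    cfg = SimConfig(n_samples=5, n_snps=100, n_chromosomes=3, seed=5)
    G = simulate_genotypes(cfg)
    for _, grp in G.markers.groupby("chrom"):
        assert (np.diff(grp["pos"].to_numpy()) > 0).all()
        assert (grp["pos"] > 0).all()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.1, 0.6)},
        {"ld_decay": 1.0},
        {"sigma0": 0.0},
        {"n_farms": 1},
        {"n_samples": -1},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimConfig(**kwargs)


class TestEnvironment:
    def test_degenerate_series_is_constant_baseline(self):
        cfg = SimConfig(
            n_samples=20, temp_baseline=10.0, farm_temp_baselines=(0.0,) * 7,
            temp_seasonal_amplitude=0.0, temp_noise_sd=0.0, seed=6,
        )
        env = simulate_environment(cfg, "continuous")
        assert np.all(env.values == 10.0)

    def test_identical_windows_give_identical_values_without_noise(self):
        cfg = SimConfig(
            n_samples=4, temp_baseline=5.0, farm_temp_baselines=(0.0,) * 7,
            temp_seasonal_amplitude=8.0, temp_noise_sd=0.0, seed=7,
        )
        births = np.array([2, 2, 2, 2])
        records = np.array([14, 14, 14, 14])
        env = simulate_environment(cfg, "continuous", birth_months=births, record_months=records)
        assert np.ptp(env.values) == 0.0

    def test_full_period_window_averages_sinusoid_to_baseline(self):
        cfg = SimConfig(
            n_samples=3, temp_baseline=10.0, farm_temp_baselines=(0.0,) * 7,
            temp_seasonal_amplitude=10.0, temp_noise_sd=0.0, seed=8,
        )
        births = np.array([0, 3, 7])
        records = births + 11  # 12 monthly samples: full period
        env = simulate_environment(cfg, "continuous", birth_months=births, record_months=records)
        # direct summation oracle
        for i, b in enumerate(births):
            t = np.arange(b, b + 12)
            expected = (10.0 + 10.0 * np.sin(2 * np.pi * t / 12)).mean()
            assert env.values[i] == pytest.approx(expected, abs=1e-12)
            assert env.values[i] == pytest.approx(10.0, abs=1e-9)

    def test_record_before_birth_rejected(self):
        cfg = SimConfig(n_samples=2, seed=9)
        with pytest.raises(ValueError, match="record month before birth"):
            simulate_environment(
                cfg, "continuous",
                birth_months=np.array([5, 5]), record_months=np.array([4, 10]),
            )

    def test_categorical_assignment_covers_farms_roughly_uniformly(self):
        cfg = SimConfig(n_samples=700, seed=10)
        env = simulate_environment(cfg, "categorical")
        counts = np.array([(env.values == lv).sum() for lv in env.levels])
        assert len(env.levels) == 7
        assert counts.min() > 50  # ~100 expected per farm


class TestPhenotype:
    def test_null_variance_matches_sigma0(self):
        n = 5000
        cfg = SimConfig(n_samples=n, n_snps=10, sigma0=3.0, hetero_delta=0.0, seed=11)
        G = simulate_genotypes(cfg)
        env = simulate_environment(cfg, "continuous")
        y = simulate_phenotype(G, env, None, cfg)
        # chi-square oracle: sample variance of N(mu, 9) has SE sigma^2*sqrt(2/(n-1))
        se = 9.0 * np.sqrt(2.0 / (n - 1))
        assert abs(y.var(ddof=1) - 9.0) < 3 * se

    def test_heteroskedastic_variance_increases_with_environment(self):
        n = 5000
        cfg = SimConfig(n_samples=n, n_snps=2, sigma0=1.0, hetero_delta=0.8, seed=12)
        G = simulate_genotypes(cfg)
        env = simulate_environment(cfg, "continuous")
        y = simulate_phenotype(G, env, None, cfg)
        q = np.quantile(env.values, [0.25, 0.75])
        v_low = y[env.values <= q[0]].var(ddof=1)
        v_high = y[env.values >= q[1]].var(ddof=1)
        assert v_high > v_low

    def test_noise_free_identity(self):
        cfg = SimConfig(
            n_samples=50, n_snps=3, sigma0=1e-14, beta_gxe=2.0, mu0=1.5, seed=13
        )
        G = simulate_genotypes(cfg)
        e_raw = np.linspace(-2, 2, 50)
        env = EnvironmentVector(e_raw, "continuous")
        y = simulate_phenotype(G, env, None, cfg, causal_snps=[1])
        expected = 1.5 + 2.0 * G.genotypes[:, 1] * e_raw
        np.testing.assert_allclose(y, expected, atol=1e-9)

    def test_causal_index_out_of_range_rejected(self):
        cfg = SimConfig(n_samples=10, n_snps=5, seed=14)
        G = simulate_genotypes(cfg)
        env = simulate_environment(cfg, "continuous")
        with pytest.raises(ValueError, match="out of range"):
            simulate_phenotype(G, env, None, cfg, causal_snps=[5])

    def test_noise_free_fit_recovers_generative_coefficients(self):
        """The scan's model is the generative model: exact recovery without noise."""
        cfg = SimConfig(
            n_samples=300, n_snps=4, sigma0=1e-13,
            beta_g=0.7, beta_e=-0.3, beta_gxe=1.9, mu0=5.0, seed=15,
        )
        G = simulate_genotypes(cfg)
        env = simulate_environment(cfg, "continuous")
        y = simulate_phenotype(G, env, None, cfg, causal_snps=[2])
        # centered design matches the generative encoding exactly
        X = build_design(G.genotypes[:, 2], env, None, y=y, center_env=True)
        fit = fit_ols(y, X)
        assert fit.coef("snp")[0] == pytest.approx(0.7, rel=1e-10)
        assert fit.coef("env")[0] == pytest.approx(-0.3, rel=1e-10)
        assert fit.coef("snp_env")[0] == pytest.approx(1.9, rel=1e-10)
        # the centered env column shifts the intercept by beta_e * mean(E)
        assert fit.coef("intercept")[0] == pytest.approx(
            5.0 - 0.3 * env.values.mean(), rel=1e-10
        )


def test_seed_determinism_end_to_end():
    def run():
        cfg = SimConfig(n_samples=60, n_snps=40, missing_rate=0.02, hetero_delta=0.3, seed=77)
        G = simulate_genotypes(cfg)
        farms = simulate_environment(cfg, "categorical")
        temp = simulate_environment(cfg, "continuous", farms=farms)
        y = simulate_phenotype(G, temp, None, cfg, causal_snps=[3])
        return G.genotypes, np.asarray(farms.values), temp.values, y

    g1, f1, t1, y1 = run()
    g2, f2, t2, y2 = run()
    assert (g1 == g2).all()
    assert (f1 == f2).all()
    np.testing.assert_array_equal(t1, t2)
    np.testing.assert_array_equal(y1, y2)


def test_trios_obey_mendelian_transmission_without_errors():
    from gweiskit.qc import mendel_error_rate

    cfg = SimConfig(n_samples=10, n_snps=60, seed=16)
    gm, trios = simulate_trios(cfg, n_trios=50, genotyping_error_rate=0.0)
    rate = mendel_error_rate(gm, trios)
    assert np.nanmax(rate) == 0.0


def test_trio_genotyping_errors_raise_mendel_rate():
    from gweiskit.qc import mendel_error_rate

    cfg = SimConfig(n_samples=10, n_snps=60, seed=17)
    gm, trios = simulate_trios(cfg, n_trios=100, genotyping_error_rate=0.2)
    rate = mendel_error_rate(gm, trios)
    assert np.nanmean(rate) > 0.02
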