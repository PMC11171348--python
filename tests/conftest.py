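import numpy as np
import pytest

from gweiskit.simulate import SimConfig, simulate_covariates, simulate_environment, simulate_genotypes


@pytest.fixture(scope="session")
def small_cohort():
    """A reusable mid-sized cohort: genotypes, both environments, covariates."""
    cfg = SimConfig(n_samples=400, n_snps=120, ld_decay=0.2, sigma0=1.0, seed=42)
    G = simulate_genotypes(cfg)
    farms = simulate_environment(cfg, "categorical")
    temp = simulate_environment(cfg, "continuous", farms=farms)
    C = simulate_covariates(cfg)
    return cfg, G, farms, temp, C


@pytest.fixture()
def rng():
    return np.random.default_rng(20240605)
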