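"""Synthetic cohort generator for genotype-by-environment interaction scans.

Emulates the structure the analysis assumes for a multi-farm beef-cattle
cohort: an additive-coded SNP panel with tunable allele frequencies and
first-order LD, a farm assignment (categorical environment), a
per-individual mean temperature over the rearing window (continuous
environment), standard covariates (sex, age, birth weight), and phenotypes
generated from the same linear interaction model the scan fits — including
heteroskedastic residuals whose variance is log-linear in the standardized
environment, the canonical violation the sandwich estimator guards against.

Every draw is a function of ``SimConfig.seed``: an identical config yields
bit-identical genotypes, environments and phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .formats import (
    MISSING,
    GenotypeMatrix,
    SampleTable,
    _markers_frame,
    write_plink,
)

__all__ = [
    "SimConfig",
    "EnvironmentVector",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_phenotype",
    "simulate_covariates",
    "simulate_trios",
    "simulate_study",
]

DEFAULT_FARM_EFFECTS = (25.0, 0.0, 15.0, -35.0, -5.0, -15.0, 20.0)


class ConfigurationError(ValueError):
    """SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Knobs of the generative model.

    Defaults follow the cohort the generator emulates: ~1350 animals on 7
    farms, a dense autosomal chip panel (scaled down in SNP count), MAF in
    [0.05, 0.5], noticeable adjacent-marker LD, seasonal temperature with a
    +/-15 degC annual swing, and a residual SD of ~40 kg typical of growth
    phenotypes.
    """

    n_samples: int = 1350
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.6  # adjacent-marker haplotype copying probability
    n_farms: int = 7
    farm_effects: Sequence[float] = DEFAULT_FARM_EFFECTS
    temp_baseline: float = 0.0  # degC offset common to all farms
    #: annual mean temperature per farm (degC); defaults follow the latitude
    #: spread of a seven-farm cohort from ~46N (cold) to ~25N (warm)
    farm_temp_baselines: Sequence[float] = (6.0, 5.0, 7.0, 4.0, 15.0, 17.0, 16.0)
    temp_seasonal_amplitude: float = 15.0  # degC
    temp_noise_sd: float = 2.0  # degC
    trait_age_months: int = 12  # phenotype recording age (window length)
    beta_g: float = 0.0  # kg per allele
    beta_e: float = 0.0  # kg per environment unit
    beta_gxe: float = 0.0  # kg per (allele x environment unit)
    beta_c: Sequence[float] | None = None  # kg per covariate unit
    hetero_delta: float = 0.0  # log-variance slope on standardized environment
    sigma0: float = 40.0  # residual SD (kg)
    mu0: float = 200.0  # intercept (kg)
    missing_rate: float = 0.0
    n_chromosomes: int = 1
    spacing_bp: int = 3000  # mean inter-marker spacing of the emulated chip
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ConfigurationError(f"ld_decay must be in [0, 1), got {self.ld_decay}")
        if self.sigma0 <= 0:
            raise ConfigurationError("sigma0 must be > 0")
        if self.n_farms < 2:
            raise ConfigurationError("n_farms must be >= 2")
        if self.n_samples < 0 or self.n_snps < 0:
            raise ConfigurationError("n_samples and n_snps must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if len(self.farm_effects) < self.n_farms:
            raise ConfigurationError("farm_effects must have one entry per farm")


@dataclass
class EnvironmentVector:
    """Per-sample environmental measure: farm label or mean temperature."""

    values: np.ndarray
    kind: Literal["categorical", "continuous"]
    levels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.kind == "categorical":
            if self.levels is None:
                self.levels = sorted(map(str, pd.unique(self.values)))
            unknown = set(map(str, self.values)) - set(self.levels)
            if unknown:
                raise ValueError(f"categorical values outside levels: {sorted(unknown)[:5]}")
        else:
            vals = self.values.astype(float)
            if not np.isfinite(vals).all():
                raise ValueError("continuous environment must be finite")
            self.values = vals

    def __len__(self) -> int:
        return len(self.values)

    def level_index(self) -> np.ndarray:
        assert self.kind == "categorical"
        lut = {lv: i for i, lv in enumerate(self.levels)}
        return np.array([lut[str(v)] for v in self.values], dtype=int)

    def interaction_score(self) -> np.ndarray:
        """Single numeric score per sample used by the generative G x E term.

        Continuous: the centered measure, so a pure interaction SNP carries
        no marginal main effect (the signature the scan looks for).
        Categorical: the standardized level index (levels are ordered), so
        one scalar interaction slope suffices.
        """
        if self.kind == "continuous":
            v = self.values.astype(float)
            return v - v.mean()
        idx = self.level_index().astype(float)
        sd = idx.std()
        return (idx - idx.mean()) / (sd if sd > 0 else 1.0)

    def standardized(self) -> np.ndarray:
        """z-scored environment used by the heteroskedastic residual model."""
        if self.kind == "continuous":
            v = self.values.astype(float)
            sd = v.std()
            return (v - v.mean()) / (sd if sd > 0 else 1.0)
        return self.interaction_score()


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw an n x m additive-coded panel with first-order haplotype copying.

    Haplotypes carry a latent uniform per marker; with probability
    ``ld_decay`` the latent is copied from the adjacent marker on the same
    chromosome, otherwise redrawn.  The allele is the latent thresholded at
    the marker's target frequency, so marginal frequencies are exact
    Bernoulli draws while adjacent markers correlate with tunable strength.
    """
    if rng is None:
        rng = _rng(cfg, 1)
    n, m = cfg.n_samples, cfg.n_snps
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=m)

    n_chrom = max(1, cfg.n_chromosomes)
    chrom_of = np.repeat(np.arange(n_chrom), -(-m // n_chrom))[:m] if m else np.array([], dtype=int)
    pos = np.empty(m, dtype=np.int64)
    for c in range(n_chrom):
        idx = np.flatnonzero(chrom_of == c)
        pos[idx] = (np.arange(len(idx)) + 1) * cfg.spacing_bp

    hap = np.empty((2 * n, m), dtype=bool) if m else np.empty((2 * n, 0), dtype=bool)
    prev_u = None
    for j in range(m):
        u = rng.random(2 * n)
        if j > 0 and chrom_of[j] == chrom_of[j - 1] and cfg.ld_decay > 0:
            copy = rng.random(2 * n) < cfg.ld_decay
            u = np.where(copy, prev_u, u)
        hap[:, j] = u < maf[j]
        prev_u = u
    geno = (hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8)) if m else np.zeros((n, 0), np.int8)

    if cfg.missing_rate > 0 and m:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno[mask] = MISSING

    markers = _markers_frame(
        snp=[f"snp{j + 1}" for j in range(m)],
        chrom=[str(c + 1) for c in chrom_of],
        pos=pos,
        a1=["A"] * m,
        a2=["B"] * m,
    )
    samples = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(geno, samples, markers)


def simulate_environment(
    cfg: SimConfig,
    kind: Literal["categorical", "continuous"] = "continuous",
    birth_months: np.ndarray | None = None,
    record_months: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    farms: EnvironmentVector | None = None,
    farm_baselines: Sequence[float] | None = None,
) -> EnvironmentVector:
    """Draw the environmental exposure.

    Categorical: near-uniform assignment over ``n_farms`` labelled farms.
    Continuous: each individual's mean of a monthly temperature series
    (farm baseline + sinusoidal seasonal cycle + iid noise) over the window
    [birth month, recording month], both ends inclusive.  The default
    window is birth + ``trait_age_months`` with a ±1 month recording
    jitter, mirroring growth phenotypes measured within a month of their
    target age.  Month indices are absolute (month 0, 1, 2, ...); the
    seasonal term is ``A * sin(2*pi*t/12)``, so an exact 12-month window
    averages the sinusoid to zero.
    """
    if rng is None:
        rng = _rng(cfg, 2)
    n = cfg.n_samples
    if kind == "categorical":
        levels = [f"farm{i + 1}" for i in range(cfg.n_farms)]
        values = np.array(levels, dtype=object)[rng.integers(0, cfg.n_farms, size=n)]
        return EnvironmentVector(values, "categorical", levels)

    farm_idx = farms.level_index() if farms is not None else rng.integers(0, cfg.n_farms, size=n)
    if birth_months is None:
        birth_months = rng.integers(0, 12, size=n)
    birth_months = np.asarray(birth_months, dtype=int)
    if record_months is None:
        record_months = birth_months + cfg.trait_age_months + rng.integers(-1, 2, size=n)
    record_months = np.asarray(record_months, dtype=int)
    if (record_months < birth_months).any():
        bad = int((record_months < birth_months).sum())
        raise ValueError(f"record month before birth month for {bad} individual(s)")

    baselines = np.asarray(
        farm_baselines if farm_baselines is not None else cfg.farm_temp_baselines,
        dtype=float,
    )
    base = cfg.temp_baseline + baselines[farm_idx]

    values = np.empty(n, dtype=float)
    for i in range(n):
        t = np.arange(birth_months[i], record_months[i] + 1)
        series = base[i] + cfg.temp_seasonal_amplitude * np.sin(2 * np.pi * t / 12.0)
        if cfg.temp_noise_sd > 0:
            series = series + rng.normal(0.0, cfg.temp_noise_sd, size=len(t))
        values[i] = series.mean()
    return EnvironmentVector(values, "continuous")


def simulate_covariates(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Standard covariates: sex (0/1), age at recording (days), birth weight (kg)."""
    if rng is None:
        rng = _rng(cfg, 3)
    n = cfg.n_samples
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age_days": rng.normal(540.0, 60.0, size=n),
            "birth_weight": rng.normal(41.0, 5.0, size=n),
        }
    )


def simulate_phenotype(
    G: GenotypeMatrix,
    E: EnvironmentVector,
    C: pd.DataFrame | np.ndarray | None,
    cfg: SimConfig,
    causal_snps: Sequence[int] = (),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate phenotypes from the same linear interaction model the scan fits.

    y = mu0 + sum_causal (beta_g * g + beta_gxe * g * s(E)) + env main effect
        + C @ beta_c + eps,   eps_i ~ N(0, sigma0^2 * exp(hetero_delta * z_i))

    where ``s(E)`` is the numeric interaction encoding (the measure itself
    for continuous environments, the standardized level index for farms),
    the environment main effect is ``beta_e * E`` (continuous) or the
    per-farm offsets ``farm_effects`` (categorical), and ``z`` is the
    standardized environment.  ``hetero_delta = 0`` gives homoskedastic
    residuals.  Missing causal genotypes are mean-imputed.
    """
    if rng is None:
        rng = _rng(cfg, 4)
    n = G.n_samples
    if len(E) != n:
        raise ValueError("environment length does not match sample count")
    causal_snps = np.asarray(causal_snps, dtype=int)
    if causal_snps.size and (causal_snps.min() < 0 or causal_snps.max() >= G.n_snps):
        raise ValueError(f"causal SNP index out of range [0, {G.n_snps})")

    y = np.full(n, cfg.mu0, dtype=float)

    score = E.interaction_score()
    if E.kind == "continuous":
        y += cfg.beta_e * E.values
    else:
        y += np.asarray(cfg.farm_effects)[E.level_index()]

    if causal_snps.size:
        g = G.genotypes[:, causal_snps].astype(float)
        miss = g == MISSING
        if miss.any():
            col_mean = np.where(miss, np.nan, g).astype(float)
            col_mean = np.nanmean(col_mean, axis=0)
            g[miss] = np.broadcast_to(col_mean, g.shape)[miss]
        y += cfg.beta_g * g.sum(axis=1) + cfg.beta_gxe * (g * score[:, None]).sum(axis=1)

    if C is not None and cfg.beta_c is not None:
        Cm = C.to_numpy(dtype=float) if isinstance(C, pd.DataFrame) else np.asarray(C, dtype=float)
        y += Cm @ np.asarray(cfg.beta_c, dtype=float)

    z = E.standardized()
    sd = cfg.sigma0 * np.exp(0.5 * cfg.hetero_delta * z)
    y += rng.normal(0.0, 1.0, size=n) * sd
    return y


def simulate_trios(
    cfg: SimConfig,
    n_trios: int,
    genotyping_error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Parent-parent-offspring trios by Mendelian transmission.

    Children receive one random parental allele per marker (no
    recombination model); with ``genotyping_error_rate`` a child genotype
    is replaced by a uniform draw from {0,1,2}, exercising the Mendelian
    error filter.  Returns the combined panel and the trio table
    (child, father, mother IIDs).
    """
    if rng is None:
        rng = _rng(cfg, 5)
    parent_cfg = SimConfig(
        **{**cfg.__dict__, "n_samples": 2 * n_trios, "missing_rate": 0.0}
    )
    parents = simulate_genotypes(parent_cfg, rng=rng)
    m = parents.n_snps
    maf = parents.allele_freq()

    def transmit(g_parent: np.ndarray) -> np.ndarray:
        # allele passed on: for het parents a fair coin, hom parents forced
        coin = rng.random(g_parent.shape) < 0.5
        return np.where(g_parent == 1, coin.astype(np.int8), (g_parent // 2).astype(np.int8))

    fathers = parents.genotypes[0::2]
    mothers = parents.genotypes[1::2]
    children = transmit(fathers) + transmit(mothers)
    if genotyping_error_rate > 0:
        flip = rng.random(children.shape) < genotyping_error_rate
        children = np.where(flip, rng.integers(0, 3, size=children.shape, dtype=np.int8), children)

    geno = np.vstack([children, fathers, mothers]).astype(np.int8)
    samples = (
        [f"child{i + 1}" for i in range(n_trios)]
        + [f"father{i + 1}" for i in range(n_trios)]
        + [f"mother{i + 1}" for i in range(n_trios)]
    )
    gm = GenotypeMatrix(geno, samples, parents.markers.copy())
    trios = pd.DataFrame(
        {
            "child": [f"child{i + 1}" for i in range(n_trios)],
            "father": [f"father{i + 1}" for i in range(n_trios)],
            "mother": [f"mother{i + 1}" for i in range(n_trios)],
        }
    )
    return gm, trios


@dataclass
class StudyData:
    """One synthetic cohort, ready for the pipeline."""

    genotypes: GenotypeMatrix
    farms: EnvironmentVector
    temperature: EnvironmentVector
    covariates: pd.DataFrame
    phenotype: np.ndarray
    causal_snps: np.ndarray
    config: SimConfig

    def sample_frame(self, phenotype_name: str = "weight") -> pd.DataFrame:
        df = pd.DataFrame({"IID": self.genotypes.samples})
        df[phenotype_name] = self.phenotype
        df["sex"] = self.covariates["sex"].to_numpy()
        df["age_days"] = self.covariates["age_days"].to_numpy()
        df["birth_weight"] = self.covariates["birth_weight"].to_numpy()
        df["farm"] = self.farms.values
        df["mean_temp"] = self.temperature.values
        return df

    def write(self, outdir: str | Path, prefix: str = "cohort", phenotype_name: str = "weight") -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_plink(self.genotypes, outdir / prefix)
        table_path = outdir / f"{prefix}_samples.tsv"
        self.sample_frame(phenotype_name).to_csv(table_path, sep="\t", index=False)
        cfg_path = outdir / f"{prefix}_simconfig.yaml"
        cfg = {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in self.config.__dict__.items()}
        cfg_path.write_text(yaml.safe_dump(cfg))
        return {
            "plink_prefix": str(outdir / prefix),
            "sample_table": str(table_path),
            "config": str(cfg_path),
        }


def simulate_study(
    cfg: SimConfig,
    environment: Literal["categorical", "continuous"] = "continuous",
    causal_snps: Sequence[int] = (),
) -> StudyData:
    """Generate a full cohort: genotypes, farms, temperatures, covariates, phenotype."""
    G = simulate_genotypes(cfg)
    farms = simulate_environment(cfg, "categorical")
    temp = simulate_environment(cfg, "continuous", farms=farms)
    C = simulate_covariates(cfg)
    E = farms if environment == "categorical" else temp
    y = simulate_phenotype(G, E, C, cfg, causal_snps=causal_snps)
    return StudyData(G, farms, temp, C, y, np.asarray(causal_snps, dtype=int), cfg)
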