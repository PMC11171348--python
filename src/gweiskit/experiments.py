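"""Calibration experiments validating the interaction scan end to end.

These are the package's equivalent of the validation workflow a G×E study
runs before trusting its scan: type-I error of the robust vs model-based
interaction test under a heteroskedastic null, LD score regression
intercepts for both statistic flavors on an LD panel, recovery and power
for injected interaction effects, heritability recovery for the mixed
model, and null uniformity of the gene and gene-set aggregation.  Every
experiment builds its cohort from :mod:`gweiskit.simulate`, runs the real
analysis code, and returns plain numbers.

Problem sizes default to desk scale (a thousand samples, a few thousand
markers) so a full run takes minutes on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import genotype_pca
from .diagnostics import chi2_from_p, ldsc_intercept
from .formats import GeneAnnotation
from .genes import gene_set_competitive, run_gene_analysis
from .gweis import interaction_scan
from .ld import ld_scores
from .lmm import compute_grm, fit_null_reml, lmm_assoc
from .pipeline import significance_thresholds
from .simulate import (
    SimConfig,
    simulate_covariates,
    simulate_environment,
    simulate_genotypes,
    simulate_phenotype,
)

__all__ = [
    "build_cohort",
    "type_one_error",
    "ldsc_comparison",
    "gxe_recovery",
    "heritability_recovery",
    "gene_level_null",
]

N_PCS = 20  # covariate set: sex, age, birth weight + 20 genotype PCs


def build_cohort(cfg: SimConfig, n_pcs: int = N_PCS):
    """Genotypes, farms, temperature exposure and covariates (incl. PCs)."""
    G = simulate_genotypes(cfg)
    farms = simulate_environment(cfg, "categorical")
    temp = simulate_environment(cfg, "continuous", farms=farms)
    C = simulate_covariates(cfg)
    if n_pcs > 0:
        C = pd.concat([C, genotype_pca(G, n_pcs)], axis=1)
    return G, farms, temp, C


def _null_phenotypes(cfg: SimConfig, G, env, C, n_replicates: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1001]))
    return np.column_stack(
        [simulate_phenotype(G, env, C, cfg, causal_snps=(), rng=rng) for _ in range(n_replicates)]
    )


def type_one_error(
    seed: int,
    n: int = 1000,
    m: int = 2000,
    n_replicates: int = 200,
    hetero_delta: float = 0.8,
    alpha: float = 0.05,
) -> dict:
    """Empirical rejection rates of the interaction test under a null with
    environment-dependent residual variance (no G×E anywhere).

    One genome replicate, many phenotype replicates.  Returns the robust
    (default flavor) and model-based rates at ``alpha`` plus the binomial
    95% CI half-width for a scan of m tests.
    """
    cfg = SimConfig(
        n_samples=n, n_snps=m, ld_decay=0.0, hetero_delta=hetero_delta, seed=seed
    )
    G, farms, temp, C = build_cohort(cfg)
    Y = _null_phenotypes(cfg, G, temp, None, n_replicates, seed)
    res = interaction_scan(G, temp, C, Y)
    rej_robust = res["p_robust"] < alpha
    rej_model = res["p_model"] < alpha
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / m)
    return {
        "robust_rate": float(rej_robust.mean()),
        "model_rate": float(rej_model.mean()),
        "robust_rate_replicate_se": float(rej_robust.mean(axis=0).std(ddof=1) / np.sqrt(n_replicates)),
        "ci_low": alpha - half,
        "ci_high": alpha + half,
        "alpha": alpha,
        "n_tests": int(rej_robust.size),
        "m": m,
        "n_replicates": n_replicates,
    }


def ldsc_comparison(
    seed: int,
    n: int = 1000,
    m: int = 5000,
    n_replicates: int = 10,
    ld_decay: float = 0.6,
    hetero_delta: float = 0.8,
    window_bp: int = 1_000_000,
) -> dict:
    """LD score regression intercepts for robust vs model-based statistics
    on a heteroskedastic null with an LD panel (replicate average)."""
    cfg = SimConfig(
        n_samples=n, n_snps=m, ld_decay=ld_decay, hetero_delta=hetero_delta, seed=seed
    )
    G, farms, temp, C = build_cohort(cfg)
    Y = _null_phenotypes(cfg, G, temp, None, n_replicates, seed)
    res = interaction_scan(G, temp, C, Y)
    ell = ld_scores(G, window_bp=window_bp)
    icpt = {"robust": [], "model": []}
    for tag, key in (("robust", "p_robust"), ("model", "p_model")):
        for t in range(n_replicates):
            fit = ldsc_intercept(chi2_from_p(res[key][:, t]), ell)
            icpt[tag].append(fit.intercept)
    return {
        "robust_intercept": float(np.mean(icpt["robust"])),
        "model_intercept": float(np.mean(icpt["model"])),
        "robust_intercepts": [float(v) for v in icpt["robust"]],
        "model_intercepts": [float(v) for v in icpt["model"]],
        "m": m,
        "n_replicates": n_replicates,
    }


def gxe_recovery(
    seed: int,
    n: int = 2000,
    m: int = 500,
    n_causal: int = 20,
    betas: tuple[float, ...] = (0.5, 1.0, 2.0),
    n_replicates: int = 25,
) -> dict:
    """Bias and power for injected interaction effects.

    ``n_causal`` SNPs carry a G×E slope of ``beta`` kg per (allele × °C);
    each grid point is measured over phenotype replicates.  Power counts
    causal SNPs passing the suggestive threshold 1/m.  The covariate set
    omits genotype PCs: PCs of a desk-scale panel place ~n_pcs/m of any
    causal signal inside the PC×E nuisance columns, visibly attenuating
    the estimate, whereas at chip scale the leakage is negligible.
    """
    base = SimConfig(n_samples=n, n_snps=m, ld_decay=0.0, seed=seed)
    G, farms, temp, C = build_cohort(base, n_pcs=0)
    rng_causal = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    causal = np.sort(rng_causal.choice(m, size=n_causal, replace=False))
    suggestive, _ = significance_thresholds(m)
    out: dict = {"betas": list(betas), "bias": [], "bias_mc_se": [], "power": [],
                 "suggestive_threshold": suggestive, "n_causal": n_causal,
                 "n_replicates": n_replicates}
    for b in betas:
        cfg = SimConfig(n_samples=n, n_snps=m, ld_decay=0.0, beta_gxe=b, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 11, int(b * 1000)]))
        Y = np.column_stack(
            [simulate_phenotype(G, temp, None, cfg, causal_snps=causal, rng=rng)
             for _ in range(n_replicates)]
        )
        res = interaction_scan(G, temp, C, Y)
        est = res["beta"][causal]  # n_causal x r
        # replicates share the genome, so each causal SNP carries a fixed
        # conditional offset; the independent unit for the MC SE is the SNP
        per_snp_err = est.mean(axis=1) - b
        out["bias"].append(float(per_snp_err.mean()))
        out["bias_mc_se"].append(float(per_snp_err.std(ddof=1) / np.sqrt(n_causal)))
        out["power"].append(float((res["p_robust"][causal] < suggestive).mean()))
    return out


def heritability_recovery(
    seed: int,
    n: int = 1000,
    m: int = 2000,
    h2: float = 0.5,
) -> dict:
    """REML heritability estimate on a polygenic phenotype of known h²."""
    cfg = SimConfig(n_samples=n, n_snps=m, ld_decay=0.0, seed=seed)
    G = simulate_genotypes(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    W = G.genotypes.astype(float)
    W = (W - W.mean(axis=0)) / W.std(axis=0)
    g_eff = W @ rng.normal(0.0, np.sqrt(h2 / m), size=m)
    y = g_eff + rng.normal(0.0, np.sqrt(1 - h2), size=n)
    K = compute_grm(G)
    null = fit_null_reml(y, None, K)
    return {"h2_true": h2, "h2_hat": float(null.heritability), "n": n, "m": m}


def gene_level_null(
    seed: int,
    n: int = 500,
    m: int = 3000,
    snps_per_gene: int = 3,
    n_sets: int = 50,
    genes_per_set: int = 20,
    ld_decay: float = 0.3,
) -> dict:
    """Uniformity of gene and competitive set p-values under a global null.

    Genes tile the panel in disjoint blocks of ``snps_per_gene`` markers;
    sets are random gene collections.  Returns Kolmogorov–Smirnov p-values
    against the uniform distribution.
    """
    cfg = SimConfig(n_samples=n, n_snps=m, ld_decay=ld_decay, seed=seed)
    G, farms, temp, C = build_cohort(cfg, n_pcs=0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    y = simulate_phenotype(G, temp, None, cfg, causal_snps=(), rng=rng)
    res = interaction_scan(G, temp, C, y)
    summary = pd.DataFrame({"P_ROBUST": res["p_robust"]})

    pos = G.markers["pos"].to_numpy()
    n_genes = m // snps_per_gene
    rows = []
    for i in range(n_genes):
        lo, hi = i * snps_per_gene, (i + 1) * snps_per_gene - 1
        rows.append({"gene_id": f"G{i}", "chrom": G.markers["chrom"].iloc[lo],
                     "start": int(pos[lo]), "stop": int(pos[hi])})
    ann = GeneAnnotation(pd.DataFrame(rows))
    gene_res = run_gene_analysis(summary, G, ann, window_bp=0)
    sets = {
        f"S{k}": [f"G{g}" for g in rng.choice(n_genes, size=genes_per_set, replace=False)]
        for k in range(n_sets)
    }
    set_res = gene_set_competitive(gene_res, sets)
    ks_gene = stats.kstest(gene_res["P"].to_numpy(), "uniform").pvalue
    ok = set_res["STATUS"] == "ok"
    ks_set = stats.kstest(set_res.loc[ok, "P"].to_numpy(), "uniform").pvalue
    return {
        "ks_gene_p": float(ks_gene),
        "ks_set_p": float(ks_set),
        "n_genes": int(len(gene_res)),
        "n_sets": int(ok.sum()),
    }
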