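# gweiskit

Genome-wide genotype-by-environment interaction scans (GWEIS) with
heteroskedasticity-robust inference, for quantitative traits in structured
livestock cohorts — e.g. growth weights of beef cattle raised on farms with
very different climates.

A conventional GWAS asks whether a variant shifts the phenotype on average.
A GWEIS asks whether a variant's effect *depends on the environment*: a
genotype that is superior on a cold northern farm may be inferior on a warm
southern one, leaving no marginal main effect for GWAS to find.  The
statistical catch is that trait variance typically also changes with the
environment, and that heteroskedasticity inflates the naive interaction
test genome-wide.  This package implements the scan with sandwich
(Huber–White) standard errors, the surrounding QC and baseline machinery,
and the gene- and pathway-level aggregation of interaction signals.

## The model

For each SNP `j` the phenotype of individual `i` is modelled as

    y_i = μ0 + βg·G_ij + βe·E_i + βgxe·G_ij·E_i + βc'C_i + βcxg'C_i·G_ij + βcxe'C_i·E_i + ε_i

where `G_ij ∈ {0,1,2}` is an allele count, `E_i` the environmental measure
(farm, treatment-coded; or per-individual mean temperature, centered), and
`C_i` the covariates (sex, age, birth weight, genotype PCs), whose SNP and
environment interactions are included to block confounded covariate
interactions.  The parameter of interest is `βgxe`.  Its variance is
estimated both classically (`σ̂²(X'X)⁻¹`) and with the sandwich estimator

    (X'X)⁻¹ X' diag(c·w_i·e_i²) X (X'X)⁻¹

which permits a distinct residual variance per observation.  Flavors HC0,
HC1, HC2, HC3 and the default `BM` (Bell–McCaffrey: HC2 weights plus a
Satterthwaite reference df for the t test) are available; both the robust
and the model-based p-value are always reported so their divergence can be
diagnosed (QQ tables, genomic inflation factor λ_GC, LD score regression
intercepts).

Around the scan: PLINK BED/BIM/FAM I/O, marker/sample QC (MAF, call rate,
exact Hardy–Weinberg test, Mendelian error over trios, sample
missingness), an EMMAX-style mixed-model GWAS baseline (GRM + REML) for
the "no main effect" cross-check, greedy LD clumping for independent-hit
reporting, and MAGMA-style gene-based (snp-wise mean with an LD-aware
null) and competitive gene-set analyses.  A synthetic-cohort generator
reproduces the study structure (7 farms across a latitude gradient,
seasonal temperature exposure over the rearing window, heteroskedastic
residuals), so everything is testable without any data download.

## Worked example

```python
from pathlib import Path
from gweiskit.simulate import SimConfig, simulate_study
from gweiskit.pipeline import RunConfig, run_pipeline

d = Path("demo"); d.mkdir(exist_ok=True)
cfg = SimConfig(n_samples=500, n_snps=2000, seed=7, beta_gxe=2.0, sigma0=25.0)
study = simulate_study(cfg, environment="continuous", causal_snps=[1000])
study.write(d, prefix="cohort")

rc = RunConfig(
    plink_prefix=str(d / "cohort"), sample_table=str(d / "cohort_samples.tsv"),
    trait="weight", environment_name="mean_temp", environment_kind="continuous",
    n_pcs=10, stages=["qc", "gweis", "gwas", "diagnostics", "clump"],
    ld_window_bp=200_000, outdir=str(d / "run"), seed=7,
)
run_pipeline(rc)
```

prints, stage by stage:

```
[load] n_samples=500 n_snps=2000
[qc] n_samples=500 n_snps=1988 position_missing=0 duplicate=0 call_rate=0 maf=12 hwe=0 mendel=0
[thresholds] m=1988 suggestive=0.000503 bonferroni=2.52e-05
[gweis] n_snps=1988 n_suggestive=2
[gwas] h2=0.121 n_snps=1988
[clump] n_index=1988 n_suggestive=2
```

QC removed 12 low-MAF markers; thresholds (1/m and 0.05/m) derive from the
post-QC count.  The top of `run/gweis.tsv`, sorted by the robust
interaction p-value:

```
    SNP      BP     BETA  SE_ROBUST  P_ROBUST   P_GWAS
snp1001 3003000 1.725501   0.369587  0.000006 0.535666
 snp429 1287000 1.465366   0.400265  0.000353 0.537759
```

The injected interaction SNP (`snp1001`, true βgxe = 2 kg per allele·°C)
leads the scan below the suggestive threshold while its mixed-model GWAS
main-effect p-value is 0.54 — the signature of an effect that re-ranks
across environments and is invisible to a main-effect scan.

The same stages are available from a shell via the `gweiskit` CLI
(`simulate`, `qc`, `gweis`, `gwas`, `diagnostics`, `clump`, `genes`,
`genesets`, `run-all`).

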