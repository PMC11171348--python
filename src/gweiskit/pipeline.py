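"""End-to-end orchestration: QC → PCs/design → interaction scan (+ mixed-model
main-effect baseline) → inflation diagnostics → clumping → gene and gene-set
aggregation, driven by one YAML config, with a run manifest recording per-stage
output hashes, post-QC counts, the thresholds actually applied, and the seed.

Multiple-testing thresholds follow the dual-threshold convention: a
"suggestive" threshold of 1/m and a Bonferroni threshold of alpha/m, always
derived from this run's own post-QC marker / gene / set counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import genotype_pca
from .diagnostics import chi2_from_p, genomic_inflation, ldsc_intercept, qq_table
from .formats import (
    SampleTable,
    read_gene_annotation,
    read_gene_sets,
    read_plink,
    read_sample_table,
)
from .genes import gene_set_competitive, run_gene_analysis
from .gweis import run_gweis
from .ld import clump, ld_scores
from .lmm import compute_grm, fit_null_reml, lmm_assoc
from .qc import QCThresholds, apply_qc
from .simulate import EnvironmentVector

ALL_STAGES = ("qc", "gweis", "gwas", "diagnostics", "clump", "genes", "genesets")


class ConfigError(ValueError):
    """Invalid run configuration."""


def significance_thresholds(m_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """(suggestive, bonferroni) = (1/m, alpha/m) at full precision."""
    if m_tests <= 0:
        raise ValueError("m_tests must be positive")
    return 1.0 / m_tests, alpha / m_tests


@dataclass
class RunConfig:
    plink_prefix: str
    sample_table: str
    trait: str
    environment_name: str
    environment_kind: str  # "categorical" | "continuous"
    covariates: list[str] = field(default_factory=lambda: ["sex", "age_days", "birth_weight"])
    n_pcs: int = 20
    reference_level: str | None = None
    gene_annotation: str | None = None
    gene_sets: str | None = None
    alpha: float = 0.05
    robust_flavor: str = "BM"
    clump_r2: float = 0.8
    clump_window_bp: int = 1_000_000
    gene_window_bp: int = 50_000
    ld_window_bp: int = 1_000_000
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    outdir: str = "gweis_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def validate(self) -> None:
        for p in (
            Path(self.plink_prefix).with_suffix(".bed"),
            Path(self.sample_table),
            *( [Path(self.gene_annotation)] if self.gene_annotation else [] ),
            *( [Path(self.gene_sets)] if self.gene_sets else [] ),
        ):
            if not p.exists():
                raise ConfigError(f"input file missing: {p}")
        if self.environment_kind not in ("categorical", "continuous"):
            raise ConfigError(f"environment_kind must be categorical/continuous, got {self.environment_kind}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "trait": config.trait,
        "environment": {"name": config.environment_name, "kind": config.environment_kind},
        "stages": {},
        "thresholds": {},
    }
    outputs: dict[str, Path] = {}

    def log(stage: str, **info) -> None:
        manifest["stages"][stage] = {**manifest["stages"].get(stage, {}), **info}
        print(f"[{stage}] " + " ".join(f"{k}={v}" for k, v in info.items()))

    G = read_plink(config.plink_prefix)
    table = read_sample_table(
        config.sample_table, config.trait, config.covariates, config.environment_name
    )
    table = table.aligned_to(G.samples)
    log("load", n_samples=G.n_samples, n_snps=G.n_snps)

    if "qc" in config.stages:
        G, report = apply_qc(G, QCThresholds())
        table = table.aligned_to(G.samples)
        qc_prefix = out / "qc_report"
        report.write(qc_prefix)
        outputs["qc"] = qc_prefix.with_suffix(".json")
        log("qc", n_samples=G.n_samples, n_snps=G.n_snps, **report.exclusions)

    complete = table.complete_mask()
    n_flagged = int((~complete).sum())
    if n_flagged:
        keep = np.flatnonzero(complete)
        G = G.subset(sample_idx=keep)
        table = table.aligned_to(G.samples)
    log("complete_case", n_flagged=n_flagged, n_used=G.n_samples)

    df = table.table
    covs = df[config.covariates].astype(float).reset_index(drop=True)
    if config.n_pcs > 0:
        pcs = genotype_pca(G, config.n_pcs)
        covs = pd.concat([covs, pcs.reset_index(drop=True)], axis=1)
    y = df[config.trait].to_numpy(dtype=float)
    if config.environment_kind == "categorical":
        env = EnvironmentVector(df[config.environment_name].astype(str).to_numpy(), "categorical")
    else:
        env = EnvironmentVector(df[config.environment_name].to_numpy(dtype=float), "continuous")

    suggestive, bonferroni = significance_thresholds(G.n_snps, config.alpha)
    manifest["thresholds"]["snp"] = {
        "m": G.n_snps, "suggestive": suggestive, "bonferroni": bonferroni,
    }
    log("thresholds", m=G.n_snps, suggestive=f"{suggestive:.3g}", bonferroni=f"{bonferroni:.3g}")

    summary = None
    if "gweis" in config.stages:
        summary = run_gweis(
            G, env, covs, y,
            robust_flavor=config.robust_flavor, reference_level=config.reference_level,
        )
        path = out / "gweis.tsv"
        summary.to_csv(path, sep="\t", index=False)
        outputs["gweis"] = path
        n_hit = int((summary["P_ROBUST"] < suggestive).sum())
        log("gweis", n_snps=len(summary), n_suggestive=n_hit)

    gwas = None
    if "gwas" in config.stages:
        grm = compute_grm(G)
        null = fit_null_reml(y, covs, grm)
        gwas = lmm_assoc(G, y, covs, null)
        path = out / "gwas.tsv"
        gwas.to_csv(path, sep="\t", index=False)
        outputs["gwas"] = path
        log("gwas", h2=f"{null.heritability:.3f}", n_snps=len(gwas))
        if summary is not None:
            summary = summary.merge(
                gwas[["SNP", "P"]].rename(columns={"P": "P_GWAS"}), on="SNP", how="left"
            )
            summary.to_csv(out / "gweis.tsv", sep="\t", index=False)

    if "diagnostics" in config.stages and summary is not None:
        ok = summary["STATUS"] == "ok"
        ell = ld_scores(G, window_bp=config.ld_window_bp)
        diag = {}
        for tag, col in (("model", "P"), ("robust", "P_ROBUST")):
            p = summary.loc[ok, col].to_numpy()
            qq = qq_table(p)
            qq.to_csv(out / f"qq_{tag}.tsv", sep="\t", index=False)
            fit = ldsc_intercept(chi2_from_p(p), ell[ok.to_numpy()])
            diag[tag] = {
                "lambda_gc": genomic_inflation(p),
                "ldsc_intercept": fit.intercept,
                "ldsc_intercept_se": fit.intercept_se,
                "ldsc_slope": fit.slope,
            }
        path = out / "diagnostics.json"
        path.write_text(json.dumps(diag, indent=2))
        outputs["diagnostics"] = path
        log("diagnostics", **{f"{t}_intercept": f"{d['ldsc_intercept']:.3f}" for t, d in diag.items()})

    if "clump" in config.stages and summary is not None:
        clumped = clump(summary, G, r2_threshold=config.clump_r2, window_bp=config.clump_window_bp)
        path = out / "clumps.tsv"
        clumped.to_csv(path, sep="\t", index=False)
        outputs["clump"] = path
        log("clump", n_index=len(clumped),
            n_suggestive=int((clumped["P"] < suggestive).sum()))

    gene_results = None
    if "genes" in config.stages and summary is not None and config.gene_annotation:
        ann = read_gene_annotation(config.gene_annotation)
        gene_results = run_gene_analysis(summary, G, ann, window_bp=config.gene_window_bp)
        if gwas is not None:
            gwas_genes = run_gene_analysis(
                summary.assign(P_ROBUST=summary["P_GWAS"]), G, ann,
                window_bp=config.gene_window_bp,
            )
            gene_results = gene_results.merge(
                gwas_genes[["GENE", "P"]].rename(columns={"P": "P_GWAS"}), on="GENE", how="left"
            )
        path = out / "genes.tsv"
        gene_results.to_csv(path, sep="\t", index=False)
        outputs["genes"] = path
        g_sugg, g_bonf = significance_thresholds(len(gene_results), config.alpha)
        manifest["thresholds"]["gene"] = {
            "m": len(gene_results), "suggestive": g_sugg, "bonferroni": g_bonf,
        }
        log("genes", n_genes=len(gene_results), bonferroni=f"{g_bonf:.3g}")

    if "genesets" in config.stages and gene_results is not None and config.gene_sets:
        ann = read_gene_annotation(config.gene_annotation)
        sets = read_gene_sets(config.gene_sets, ann)
        set_results = gene_set_competitive(gene_results, sets)
        if gwas is not None and "P_GWAS" in gene_results.columns:
            alt = gene_results.copy()
            from scipy import stats as _st

            alt["Z"] = _st.norm.isf(np.clip(alt["P_GWAS"], np.finfo(float).tiny, 1.0))
            alt_sets = gene_set_competitive(alt, sets)
            set_results = set_results.merge(
                alt_sets[["SET", "P"]].rename(columns={"P": "P_GWAS"}), on="SET", how="left"
            )
        path = out / "genesets.tsv"
        set_results.to_csv(path, sep="\t", index=False)
        outputs["genesets"] = path
        analyzed = int((set_results["STATUS"] == "ok").sum())
        if analyzed:
            s_sugg, s_bonf = significance_thresholds(analyzed, config.alpha)
            manifest["thresholds"]["gene_set"] = {
                "m": analyzed, "suggestive": s_sugg, "bonferroni": s_bonf,
            }
        log("genesets", n_sets=len(set_results), n_analyzed=analyzed)

    manifest["outputs"] = {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
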