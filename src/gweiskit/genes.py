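"""Gene-level and gene-set aggregation of interaction p-values.

SNPs map to a gene when they fall within 50 kb of its transcript bounds
(inclusive, multi-gene assignment allowed).  The gene statistic is the mean
of the χ²₁-transformed SNP p-values ("snp-wise mean").  Its null must
respect inter-SNP LD: for z-scores with correlation matrix R the mean of
squares has E[T] = 1 and Var(T) = (2/m²) Σᵢⱼ rᵢⱼ² (normal fourth-moment
identity cov(zᵢ², zⱼ²) = 2rᵢⱼ²), which we moment-match to a scaled
chi-square (Satterthwaite): T ~ χ²_ν/ν with ν = 2/Var(T).  Independence
recovers the χ²_m closed form; perfect LD collapses to ν = 1 and the gene
p equals the single-SNP p.  A seeded multivariate-normal sampling fallback
covers degenerate moments.

Competitive gene-set analysis regresses the gene Z-score (probit of
1 − gene p) on set membership plus gene-size covariates (SNP count and its
log), reporting a one-sided p for a positive membership coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GeneAnnotation, GeneSetCollection, GenotypeMatrix
from .ld import snp_correlation

__all__ = [
    "map_snps_to_genes",
    "gene_test_snpwise_mean",
    "run_gene_analysis",
    "gene_set_competitive",
    "GeneResult",
]

DEFAULT_WINDOW_BP = 50_000


@dataclass
class GeneResult:
    gene_id: str
    n_snps: int
    stat: float  # mean chi-square
    p: float
    z: float  # probit(1 - p)
    method: str  # "satterthwaite" or "sampling"


def map_snps_to_genes(
    markers: pd.DataFrame,
    genes: GeneAnnotation,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> dict[str, np.ndarray]:
    """gene_id -> sorted marker indices with pos in [start−w, stop+w] (inclusive)."""
    out: dict[str, np.ndarray] = {}
    chrom = markers["chrom"].astype(str).to_numpy()
    pos = markers["pos"].to_numpy()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        o = np.argsort(pos[idx], kind="mergesort")
        by_chrom[c] = (idx[o], pos[idx[o]])
    for row in genes.table.itertuples():
        c = str(row.chrom)
        if c not in by_chrom:
            out[row.gene_id] = np.array([], dtype=int)
            continue
        idx, cpos = by_chrom[c]
        lo = np.searchsorted(cpos, row.start - window_bp, side="left")
        hi = np.searchsorted(cpos, row.stop + window_bp, side="right")
        out[row.gene_id] = np.sort(idx[lo:hi])
    return out


def _psd_correlation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    if vals.min() < -1e-4:
        raise ValueError(f"correlation matrix far from PSD (min eigenvalue {vals.min():.3g})")
    vals = np.clip(vals, tol, None)
    R2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def gene_test_snpwise_mean(
    snp_p: np.ndarray,
    R: np.ndarray | None = None,
    gene_id: str = "",
    n_draws: int = 100_000,
    sampling_seed: int = 12345,
) -> GeneResult:
    """Mean-of-χ² gene test with an LD-aware Satterthwaite null.

    ``R`` is the signed inter-SNP genotype correlation matrix (identity when
    omitted).  Single-SNP genes return the SNP p unchanged.
    """
    p = np.clip(np.asarray(snp_p, dtype=float), np.finfo(float).tiny, 1.0)
    m = len(p)
    if m == 0:
        raise ValueError("gene has no SNPs")
    chi2 = stats.chi2.isf(p, 1)
    T = float(chi2.mean())
    if m == 1:
        gene_p = float(p[0])
        return GeneResult(gene_id, 1, T, gene_p, float(stats.norm.isf(gene_p)), "exact")

    if R is None:
        sum_r2 = float(m)
        R_use = None
    else:
        if R.shape != (m, m):
            raise ValueError("R dimensions do not match the SNP list")
        R_use = _psd_correlation(R)
        sum_r2 = float((R_use**2).sum())

    var_T = 2.0 * sum_r2 / (m * m)
    nu = 2.0 / var_T
    method = "satterthwaite"
    if not np.isfinite(nu) or nu <= 0:
        method = "sampling"
    if method == "satterthwaite":
        gene_p = float(stats.chi2.sf(nu * T, nu))
    else:
        rng = np.random.default_rng(sampling_seed)
        L = np.linalg.cholesky(R_use if R_use is not None else np.eye(m))
        z = rng.standard_normal((n_draws, m)) @ L.T
        T_null = (z**2).mean(axis=1)
        gene_p = float((1 + (T_null >= T).sum()) / (n_draws + 1))
    gene_p = min(max(gene_p, np.finfo(float).tiny), 1.0)
    return GeneResult(gene_id, m, T, gene_p, float(stats.norm.isf(gene_p)), method)


def gene_test_sampling(
    snp_p: np.ndarray,
    R: np.ndarray | None,
    n_draws: int = 100_000,
    sampling_seed: int = 12345,
) -> float:
    """Empirical MVN null for the mean-of-χ² statistic (cross-check path)."""
    p = np.clip(np.asarray(snp_p, dtype=float), np.finfo(float).tiny, 1.0)
    m = len(p)
    T = float(stats.chi2.isf(p, 1).mean())
    rng = np.random.default_rng(sampling_seed)
    L = np.linalg.cholesky(_psd_correlation(R) if R is not None else np.eye(m))
    z = rng.standard_normal((n_draws, m)) @ L.T
    T_null = (z**2).mean(axis=1)
    return float((1 + (T_null >= T).sum()) / (n_draws + 1))


def run_gene_analysis(
    summary: pd.DataFrame,
    G: GenotypeMatrix,
    genes: GeneAnnotation,
    window_bp: int = DEFAULT_WINDOW_BP,
    p_column: str = "P_ROBUST",
) -> pd.DataFrame:
    """Gene-based scan: map SNPs to windows, test each gene with >= 1 SNP."""
    if len(summary) != G.n_snps:
        raise ValueError("summary rows must map one-to-one to genotype columns")
    pvals = summary[p_column].to_numpy()
    mapping = map_snps_to_genes(G.markers, genes, window_bp)
    rows = []
    for row in genes.table.itertuples():
        idx = mapping[row.gene_id]
        idx = idx[np.isfinite(pvals[idx])]
        if idx.size == 0:
            continue
        R = snp_correlation(G, idx) if idx.size > 1 else None
        res = gene_test_snpwise_mean(pvals[idx], R, gene_id=row.gene_id)
        rows.append(
            {
                "GENE": row.gene_id,
                "CHR": row.chrom,
                "START": row.start,
                "STOP": row.stop,
                "N_SNPS": res.n_snps,
                "STAT": res.stat,
                "P": res.p,
                "Z": res.z,
                "METHOD": res.method,
            }
        )
    return pd.DataFrame(rows)


def gene_set_competitive(
    gene_results: pd.DataFrame,
    sets: GeneSetCollection | dict[str, list[str]],
    min_genes: int = 2,
) -> pd.DataFrame:
    """Competitive gene-set regression over all analyzed genes.

    For each set: OLS of gene Z on [intercept, membership, n_snps,
    log(n_snps)]; the reported p is one-sided for a positive membership
    coefficient (member genes more associated than non-members).  Sets with
    fewer than ``min_genes`` analyzed member genes, or covering all genes,
    are skipped with a reason.
    """
    import statsmodels.api as sm

    set_map = sets.sets if isinstance(sets, GeneSetCollection) else sets
    genes_avail = gene_results["GENE"].to_numpy()
    z = gene_results["Z"].to_numpy(dtype=float)
    nsnp = gene_results["N_SNPS"].to_numpy(dtype=float)
    covar = np.column_stack([nsnp, np.log(nsnp)])
    # constant size covariates (e.g. uniform gene windows) are collinear
    # with the intercept; drop them rather than destabilize the fit
    covar = covar[:, covar.std(axis=0) > 1e-12]
    pos = {g: i for i, g in enumerate(genes_avail)}

    rows = []
    for set_id, members in set_map.items():
        idx = [pos[g] for g in members if g in pos]
        n_members = len(idx)
        if n_members < min_genes:
            rows.append({"SET": set_id, "N_GENES": n_members, "BETA": np.nan, "P": np.nan,
                         "STATUS": "too_few_genes"})
            continue
        if n_members >= len(genes_avail):
            rows.append({"SET": set_id, "N_GENES": n_members, "BETA": np.nan, "P": np.nan,
                         "STATUS": "covers_all_genes"})
            continue
        member = np.zeros(len(genes_avail))
        member[idx] = 1.0
        X = sm.add_constant(np.column_stack([member, covar]))
        fit = sm.OLS(z, X).fit()
        beta = float(fit.params[1])
        tstat = float(fit.tvalues[1])
        p_one = float(stats.t.sf(tstat, fit.df_resid))
        rows.append({"SET": set_id, "N_GENES": n_members, "BETA": beta,
                     "P": max(p_one, np.finfo(float).tiny), "STATUS": "ok"})
    return pd.DataFrame(rows)
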