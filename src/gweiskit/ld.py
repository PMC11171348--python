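"""Genotype-based linkage disequilibrium: pairwise r², greedy clumping,
and per-SNP LD scores.

r² is the squared Pearson correlation of additive genotype codes over
shared non-missing samples (composite LD on unphased data, the PLINK
``--r2`` convention).  Clumping reports independent index SNPs by ascending
p-value; LD scores sum bias-adjusted r² over a physical window for the LD
score regression diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeMatrix

__all__ = ["ld_r2", "clump", "ld_scores", "snp_correlation"]


def _standardize_impute(geno: np.ndarray) -> np.ndarray:
    X = geno.astype(float)
    miss = X == MISSING
    if miss.any():
        X[miss] = np.nan
        mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(mean, idx[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.nan
    return X / sd


def ld_r2(G: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Squared genotype correlation of two markers over shared non-missing samples."""
    a = G.genotypes[:, snp_i].astype(float)
    b = G.genotypes[:, snp_j].astype(float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("r2 undefined for a monomorphic marker")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def snp_correlation(G: GenotypeMatrix, snp_idx=None) -> np.ndarray:
    """Signed genotype correlation matrix (mean-imputed) for a marker subset."""
    geno = G.genotypes if snp_idx is None else G.genotypes[:, np.asarray(snp_idx)]
    X = _standardize_impute(geno)
    n = X.shape[0]
    R = (X.T @ X) / n
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def clump(
    summary: pd.DataFrame,
    G: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
    p_column: str = "P_ROBUST",
) -> pd.DataFrame:
    """Greedy p-value clumping to an independent index-SNP list.

    Repeatedly takes the smallest-p remaining SNP as an index SNP and drops
    every remaining SNP on the same chromosome within ``window_bp`` whose
    r² with it is at or above the threshold.  Ties in p break by
    (chromosome, position, marker id).  ``summary`` rows must align
    one-to-one with the genotype columns.
    """
    if len(summary) != G.n_snps:
        raise ValueError("summary rows must map one-to-one to genotype columns")
    df = summary.reset_index(drop=True).copy()
    df["_col"] = np.arange(len(df))
    usable = df[np.isfinite(df[p_column])]
    order = usable.sort_values(
        [p_column, "CHR", "BP", "SNP"], kind="mergesort"
    )["_col"].to_numpy()

    X = _standardize_impute(G.genotypes)
    n = X.shape[0]
    chrom = df["CHR"].astype(str).to_numpy()
    pos = df["BP"].to_numpy()

    alive = np.zeros(len(df), dtype=bool)
    alive[order] = True
    index_rows = []
    members: dict[int, list[int]] = {}
    for col in order:
        if not alive[col]:
            continue
        alive[col] = False
        index_rows.append(col)
        members[col] = []
        near = alive & (chrom == chrom[col]) & (np.abs(pos - pos[col]) <= window_bp)
        cand = np.flatnonzero(near)
        if cand.size:
            with np.errstate(invalid="ignore"):
                r = (X[:, cand].T @ X[:, col]) / n
            hit = cand[np.nan_to_num(r**2) >= r2_threshold]
            alive[hit] = False
            members[col].extend(hit.tolist())

    rows = df.loc[index_rows, ["SNP", "CHR", "BP", p_column]].copy()
    rows = rows.rename(columns={p_column: "P"})
    rows["N_CLUMPED"] = [len(members[c]) for c in index_rows]
    rows["MEMBERS"] = [",".join(df.loc[members[c], "SNP"]) for c in index_rows]
    return rows.reset_index(drop=True)


def ld_scores(G: GenotypeMatrix, window_bp: int = 1_000_000, chunk: int = 256) -> np.ndarray:
    """Per-SNP LD score: 1 (self) + sum of bias-adjusted r² over the window.

    The adjustment r²_adj = r² − (1 − r²)/(n − 2) removes the finite-sample
    upward bias of squared correlations, so an LD-free panel has scores
    centred at 1.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    X = _standardize_impute(G.genotypes)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for bias-adjusted r2")
    chrom = G.markers["chrom"].astype(str).to_numpy()
    pos = G.markers["pos"].to_numpy()
    ell = np.ones(m)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cpos = pos[idx]
        o = np.argsort(cpos, kind="mergesort")
        idx = idx[o]
        cpos = cpos[o]
        mc = len(idx)
        for s in range(0, mc, chunk):
            block = idx[s : s + chunk]
            bpos = cpos[s : s + chunk]
            lo = np.searchsorted(cpos, bpos[0] - window_bp, side="left")
            hi = np.searchsorted(cpos, bpos[-1] + window_bp, side="right")
            neigh = idx[lo:hi]
            R = (X[:, neigh].T @ X[:, block]) / n  # (hi-lo) x |block|
            r2 = R**2
            adj = r2 - (1.0 - r2) / (n - 2)
            within = np.abs(cpos[lo:hi][:, None] - bpos[None, :]) <= window_bp
            not_self = neigh[:, None] != block[None, :]
            ell[block] += np.where(within & not_self, adj, 0.0).sum(axis=0)
    return ell
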