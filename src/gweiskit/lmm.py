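"""Main-effect GWAS baseline: univariate linear mixed model.

The phenotype is modelled as y = X beta + u + e with u ~ N(0, K sigma_a^2)
for a genomic relationship matrix K and e ~ N(0, I sigma_e^2).  Variance
components are estimated once on the null (no-SNP) model by REML after a
single eigendecomposition of K, profiling the ratio lambda =
sigma_a^2 / sigma_e^2 on a log10 grid refined by bounded scalar
minimization.  Per-SNP tests then hold the ratio fixed and perform
generalized least squares in the whitened space (the EMMAX approximation,
adequate for checking that interaction hits lack main effects).

With K = I the variance split is unidentifiable (V is proportional to I);
by convention lambda is returned at the lower search bound and the per-SNP
tests collapse exactly to ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .formats import MISSING, GenotypeMatrix

__all__ = ["GRM", "NullModel", "compute_grm", "fit_null_reml", "lmm_assoc"]

LOG10_LAMBDA_BOUNDS = (-5.0, 5.0)


@dataclass
class GRM:
    matrix: np.ndarray
    sample_ids: list[str]
    n_snps_used: int
    method: str = "centered_scaled"

    def write(self, prefix: str) -> None:
        """Raw float64 row-major matrix + one IID per line (documented layout)."""
        np.save(f"{prefix}.grm.npy", self.matrix)
        with open(f"{prefix}.grm.ids", "w") as fh:
            fh.write("\n".join(self.sample_ids) + "\n")


@dataclass
class NullModel:
    sigma_a2: float
    sigma_e2: float
    log10_lambda: float
    beta_fixed: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    X_rot: np.ndarray
    y_rot: np.ndarray
    reml_loglik: float

    @property
    def heritability(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else 0.0


def _standardized(G: GenotypeMatrix) -> np.ndarray:
    W = G.genotypes.astype(float)
    miss = W == MISSING
    if miss.any():
        W[miss] = np.nan
        mean = np.nanmean(W, axis=0)
        idx = np.where(np.isnan(W))
        W[idx] = np.take(mean, idx[1])
    W -= W.mean(axis=0)
    sd = W.std(axis=0)
    if (sd == 0).any():
        raise ValueError("monomorphic SNPs reached GRM computation; run QC first")
    return W / sd


def compute_grm(G: GenotypeMatrix) -> GRM:
    """K = W W' / m with W the centered, variance-standardized genotypes."""
    W = _standardized(G)
    m = W.shape[1]
    K = (W @ W.T) / m
    K = (K + K.T) / 2.0
    return GRM(K, list(G.samples), m)


def _reml_neg_loglik(log10_lam: float, d: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    lam = 10.0**log10_lam
    w = lam * d + 1.0
    n, c = X.shape
    Xw = X / w[:, None]
    XtWX = X.T @ Xw
    XtWy = Xw.T @ y
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = y - X @ beta
    quad = float(r @ (r / w))
    if quad <= 0 or not np.isfinite(quad):
        return np.inf
    sigma_e2 = quad / (n - c)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - c) * np.log(sigma_e2)
        + np.log(w).sum()
        + logdet_XtWX
        + (n - c)
    )
    return -ll


def fit_null_reml(
    y: np.ndarray,
    C: pd.DataFrame | np.ndarray | None,
    K: GRM,
    n_grid: int = 64,
) -> NullModel:
    """REML variance components for the no-SNP model via eigendecomposition.

    The ratio lambda = sigma_a^2/sigma_e^2 is profiled over log10 lambda in
    [-5, 5]; a coarse grid locates the basin and Brent refines it.  A
    near-constant eigenvalue spectrum (K ∝ I) makes the profile flat; the
    lower bound is returned by convention and total variance is preserved.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if isinstance(C, pd.DataFrame):
        Cm = C.to_numpy(dtype=float)
    elif C is None:
        Cm = np.zeros((n, 0))
    else:
        Cm = np.asarray(C, dtype=float)
    X = np.column_stack([np.ones(n), Cm])
    if n <= X.shape[1]:
        raise ValueError("need more samples than fixed effects")

    d, U = np.linalg.eigh(K.matrix)
    d = np.clip(d, 0.0, None)
    y_rot = U.T @ y
    X_rot = U.T @ X

    lo, hi = LOG10_LAMBDA_BOUNDS
    if np.ptp(d) < 1e-8 * max(1.0, abs(d).max()):
        best = lo  # unidentifiable split: V ∝ I for every lambda
    else:
        grid = np.linspace(lo, hi, n_grid)
        vals = np.array([_reml_neg_loglik(g, d, X_rot, y_rot) for g in grid])
        if not np.isfinite(vals).any():
            raise RuntimeError(f"non-finite REML likelihood across lambda grid {grid}")
        i = int(np.nanargmin(vals))
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(a, b), args=(d, X_rot, y_rot), method="bounded"
        )
        best = float(res.x) if res.fun <= vals[i] else float(grid[i])

    lam = 10.0**best
    w = lam * d + 1.0
    Xw = X_rot / w[:, None]
    beta = np.linalg.solve(X_rot.T @ Xw, Xw.T @ y_rot)
    r = y_rot - X_rot @ beta
    sigma_e2 = float(r @ (r / w)) / (n - X.shape[1])
    sigma_a2 = lam * sigma_e2
    return NullModel(
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        log10_lambda=best,
        beta_fixed=beta,
        eigvals=d,
        eigvecs=U,
        X_rot=X_rot,
        y_rot=y_rot,
        reml_loglik=-_reml_neg_loglik(best, d, X_rot, y_rot),
    )


def lmm_assoc(
    G: GenotypeMatrix,
    y: np.ndarray,
    C: pd.DataFrame | np.ndarray | None,
    null: NullModel,
) -> pd.DataFrame:
    """Per-SNP GLS Wald tests with the variance ratio fixed at the null fit.

    Missing genotypes are mean-imputed (as GEMMA does).  Returns the same
    summary-statistic schema as the interaction scan (SNP, CHR, BP, A1,
    BETA, SE, P).
    """
    lam = 10.0**null.log10_lambda
    w = lam * null.eigvals + 1.0
    scale = 1.0 / np.sqrt(w)
    ystar = null.y_rot * scale
    Xstar = null.X_rot * scale[:, None]
    n, c = Xstar.shape

    W = G.genotypes.astype(float)
    miss = W == MISSING
    if miss.any():
        W[miss] = np.nan
        mean = np.nanmean(W, axis=0)
        idx = np.where(np.isnan(W))
        W[idx] = np.take(mean, idx[1])
    Gstar = (null.eigvecs.T @ W) * scale[:, None]

    Q, _ = np.linalg.qr(Xstar)
    y_r = ystar - Q @ (Q.T @ ystar)
    G_r = Gstar - Q @ (Q.T @ Gstar)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    dfres = n - c - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = float(y_r @ y_r) - beta**2 * gg
        sigma2 = rss / dfres
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    ok = gg > 1e-12
    p = np.full(G.n_snps, np.nan)
    p[ok] = np.clip(2.0 * stats.t.sf(np.abs(tstat[ok]), dfres), np.finfo(float).tiny, 1.0)
    beta[~ok] = np.nan
    se[~ok] = np.nan

    mk = G.markers
    return pd.DataFrame(
        {
            "SNP": mk["snp"],
            "CHR": mk["chrom"],
            "BP": mk["pos"],
            "A1": mk["a1"],
            "BETA": beta,
            "SE": se,
            "P": p,
        }
    )
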