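"""Per-SNP linear interaction model with model-based and sandwich covariance.

For every SNP the phenotype is regressed on the full interaction design
(see :mod:`gweiskit.design`) and the SNP×environment coefficient(s) are
tested twice: with the classical model-based covariance
sigma^2 (X'X)^-1 — valid only under homoskedasticity — and with the
Huber–White sandwich covariance

    (X'X)^-1 X' diag(c * e_i^2) X (X'X)^-1,

which stays valid when the residual variance differs across environmental
exposure.  Several finite-sample flavors are available: HC0 (c = 1), HC1
(c = n/(n−p)), the leverage-corrected HC2 (weights 1/(1−h_i)) and HC3
(1/(1−h_i)²), and the default "BM" (Bell–McCaffrey): HC2 variance with a
Satterthwaite reference degrees-of-freedom for the t test.  With ~70
design columns and cohorts of roughly 800–1200, HC0/HC1 are measurably
liberal while BM keeps the interaction test near its nominal size — the
package's own calibration experiments quantify this.  One-column
interactions use a t reference (n−p df, or the Satterthwaite df under BM);
multi-column (farm) interactions use a Wald chi-square with levels−1
degrees of freedom on the flavor's covariance.

``interaction_scan`` is the vectorized engine: it shares each SNP's design
across any number of phenotype replicates, which is what makes the
calibration experiments (hundreds of null phenotype draws) affordable.
Its output is asserted against the naive per-SNP path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .design import TERM_ORDER, DesignMatrix, build_design
from .formats import MISSING, GenotypeMatrix
from .simulate import EnvironmentVector

__all__ = [
    "FitResult",
    "fit_ols",
    "sandwich_covariance",
    "interaction_test",
    "joint_test",
    "run_gweis",
    "interaction_scan",
]


DEFAULT_FLAVOR = "BM"
_FLAVORS = ("HC0", "HC1", "HC2", "HC3", "BM")


@dataclass
class FitResult:
    design: DesignMatrix
    beta: np.ndarray
    residuals: np.ndarray
    model_cov: np.ndarray
    robust_cov: np.ndarray | None
    n_used: int
    robust_flavor: str | None = None
    inv_XtX: np.ndarray | None = None

    @property
    def df_resid(self) -> int:
        return self.n_used - self.design.p

    def coef(self, term: str) -> np.ndarray:
        return self.beta[self.design.group(term)]


def fit_ols(y: np.ndarray, X: DesignMatrix, robust_flavor: str | None = DEFAULT_FLAVOR) -> FitResult:
    """Least squares with model-based (and optionally sandwich) covariance."""
    y = np.asarray(y, dtype=float)[X.rows_used] if len(y) != X.matrix.shape[0] else np.asarray(y, dtype=float)
    A = X.matrix
    n, p = A.shape
    if n <= p:
        raise ValueError(f"n_used={n} must exceed p={p}")
    XtX = A.T @ A
    c, low = cho_factor(XtX)
    beta = cho_solve((c, low), A.T @ y)
    resid = y - A @ beta
    inv_XtX = cho_solve((c, low), np.eye(p))
    sigma2 = float(resid @ resid) / (n - p)
    model_cov = sigma2 * inv_XtX
    robust = None
    if robust_flavor is not None:
        robust = _sandwich(A, inv_XtX, resid, robust_flavor)
    return FitResult(X, beta, resid, model_cov, robust, n, robust_flavor, inv_XtX)


def _leverage(A: np.ndarray, inv_XtX: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", A @ inv_XtX, A)


def _robust_weights(flavor: str, A: np.ndarray, inv_XtX: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-observation weights w_i on e_i^2 and global scale c for a flavor."""
    n, p = A.shape
    if flavor == "HC0":
        return np.ones(n), 1.0
    if flavor == "HC1":
        return np.ones(n), n / (n - p)
    if flavor in ("HC2", "BM"):
        return 1.0 / (1.0 - _leverage(A, inv_XtX)), 1.0
    if flavor == "HC3":
        return 1.0 / (1.0 - _leverage(A, inv_XtX)) ** 2, 1.0
    raise ValueError(f"unknown sandwich flavor {flavor!r} (use one of {_FLAVORS})")


def _sandwich(A: np.ndarray, inv_XtX: np.ndarray, resid: np.ndarray, flavor: str) -> np.ndarray:
    w, c = _robust_weights(flavor, A, inv_XtX)
    meat = (A * (c * w * resid**2)[:, None]).T @ A
    V = inv_XtX @ meat @ inv_XtX
    return (V + V.T) / 2.0


def sandwich_covariance(X: DesignMatrix, residuals: np.ndarray, flavor: str = "HC1") -> np.ndarray:
    """Huber–White covariance (X'X)^-1 X' diag(c w e^2) X (X'X)^-1.

    ``flavor`` selects the finite-sample weighting: HC0 (w=1, c=1), HC1
    (w=1, c=n/(n−p)), HC2/BM (w=1/(1−h)), HC3 (w=1/(1−h)²).
    """
    A = X.matrix
    residuals = np.asarray(residuals, dtype=float)
    if residuals.shape[0] != A.shape[0]:
        raise ValueError(
            f"residual length {residuals.shape[0]} does not match design rows {A.shape[0]}"
        )
    inv_XtX = np.linalg.inv(A.T @ A)
    return _sandwich(A, inv_XtX, residuals, flavor)


def _bm_df(A: np.ndarray, inv_XtX: np.ndarray, h: np.ndarray, j: int) -> float:
    """Bell–McCaffrey Satterthwaite reference df for coefficient ``j``.

    The HC2 variance estimate for beta_j is a quadratic form e'Se with
    S = M diag(w) M, M = I − H, w_i = a_ji²/(1−h_i); under a homoskedastic
    normal reference its df is (tr S)² / tr(S²), computed here in O(np²)
    via the rank-p structure of H.
    """
    a = (A @ inv_XtX)[:, j]
    w = a**2 / (1.0 - h)
    trS = inv_XtX[j, j]
    Xw = A * np.sqrt(w)[:, None]
    B = inv_XtX @ (Xw.T @ Xw)
    trS2 = (w**2 * (1.0 - h) ** 2).sum() + ((B * B.T).sum() - (w**2 * h**2).sum())
    return float(trS**2 / trS2)


def _wald_group(fit: FitResult, J: np.ndarray, cov_choice: str) -> tuple[float, int, float]:
    V = fit.robust_cov if cov_choice == "robust" else fit.model_cov
    if V is None:
        raise ValueError("fit has no robust covariance; refit with robust_flavor set")
    b = fit.beta[J]
    sub = V[np.ix_(J, J)]
    if len(J) == 1:
        se = float(np.sqrt(sub[0, 0]))
        if se == 0.0:
            return 0.0 if b[0] == 0 else np.inf, 1, 1.0 if b[0] == 0 else 0.0
        t = float(b[0] / se)
        df: float = fit.df_resid
        if cov_choice == "robust" and fit.robust_flavor == "BM":
            A = fit.design.matrix
            df = _bm_df(A, fit.inv_XtX, _leverage(A, fit.inv_XtX), int(J[0]))
        p = float(2.0 * stats.t.sf(abs(t), df))
        return t, 1, max(p, np.finfo(float).tiny)
    try:
        w = float(b @ np.linalg.solve(sub, b))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular sub-covariance for group of size {len(J)}") from e
    p = float(stats.chi2.sf(w, len(J)))
    return w, len(J), max(p, np.finfo(float).tiny)


def interaction_test(fit: FitResult, cov_choice: str = "robust") -> tuple[float, int, float]:
    """Test the SNP×environment coefficient(s): (stat, df, p)."""
    J = fit.design.group("snp_env")
    if len(J) == 0:
        raise ValueError("design has no snp_env columns")
    return _wald_group(fit, J, cov_choice)


def joint_test(fit: FitResult, cov_choice: str = "robust") -> tuple[float, int, float]:
    """Joint Wald test of SNP main + SNP×environment effects (1+L df)."""
    Jm = fit.design.group("snp")
    Ji = fit.design.group("snp_env")
    if len(Jm) == 0 or len(Ji) == 0:
        raise ValueError("design must contain both snp and snp_env columns")
    J = np.concatenate([Jm, Ji])
    stat, df, p = _wald_group_chi2(fit, J, cov_choice)
    return stat, df, p


def _wald_group_chi2(fit: FitResult, J: np.ndarray, cov_choice: str) -> tuple[float, int, float]:
    V = fit.robust_cov if cov_choice == "robust" else fit.model_cov
    b = fit.beta[J]
    sub = V[np.ix_(J, J)]
    w = float(b @ np.linalg.solve(sub, b))
    p = float(stats.chi2.sf(w, len(J)))
    return w, len(J), max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# vectorized genome-wide engine


def _p_from_t(t: np.ndarray, df: int) -> np.ndarray:
    return np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)


def interaction_scan(
    G: GenotypeMatrix,
    E: EnvironmentVector,
    C: pd.DataFrame | np.ndarray | None,
    Y: np.ndarray,
    robust_flavor: str = DEFAULT_FLAVOR,
    test: str = "interaction",
    reference_level: str | None = None,
    center_env: bool = True,
    min_var: float = 1e-12,
) -> dict[str, np.ndarray]:
    """Fit the interaction model at every SNP for one or many phenotypes.

    ``Y`` may be (n,) or (n, r); all returned statistic arrays then have
    shape (m,) or (m, r).  The per-SNP design is built once and shared
    across phenotype columns; robust variances use the row-wise identity
    var_rob[j] = c * sum_i a_ji^2 e_i^2 with a_j the j-th row of
    (X'X)^-1 X'.
    """
    y2 = np.atleast_2d(np.asarray(Y, dtype=float).T).T  # n x r
    n, r = y2.shape
    squeeze = np.asarray(Y).ndim == 1
    if n != G.n_samples:
        raise ValueError("phenotype rows do not match sample count")

    from .design import environment_columns

    ecols, _ = environment_columns(E, reference_level, center=center_env)
    L = ecols.shape[1]
    if isinstance(C, pd.DataFrame):
        Cm = C.to_numpy(dtype=float)
    elif C is None:
        Cm = np.zeros((n, 0))
    else:
        Cm = np.asarray(C, dtype=float)
    k = Cm.shape[1]
    p = 2 + 2 * L + 2 * k + k * L

    base = np.isfinite(y2).all(axis=1)
    base &= np.isfinite(ecols).all(axis=1)
    if k:
        base &= np.isfinite(Cm).all(axis=1)

    cov_env = (
        np.hstack([Cm * ecols[:, l][:, None] for l in range(L)]) if (k and L) else np.zeros((n, 0))
    )
    geno = G.genotypes
    m = G.n_snps

    if test == "interaction":
        J_rel = np.arange(2 + L, 2 + 2 * L)  # snp_env columns
    elif test == "joint":
        J_rel = np.concatenate([[1], np.arange(2 + L, 2 + 2 * L)])
    else:
        raise ValueError(f"unknown test {test!r}")
    q = len(J_rel)
    tiny = np.finfo(float).tiny

    out = {
        "beta": np.full((m, r), np.nan),
        "se_model": np.full((m, r), np.nan),
        "se_robust": np.full((m, r), np.nan),
        "stat_model": np.full((m, r), np.nan),
        "stat_robust": np.full((m, r), np.nan),
        "p_model": np.full((m, r), np.nan),
        "p_robust": np.full((m, r), np.nan),
        "n_used": np.zeros(m, dtype=int),
        "freq": np.full(m, np.nan),
        "df": np.zeros(m, dtype=int),
        "status": np.array(["ok"] * m, dtype=object),
    }

    n_skipped = 0
    X = np.empty((int(base.sum()), p))
    for j in range(m):
        gj = geno[:, j]
        rows = base & (gj != MISSING)
        n_s = int(rows.sum())
        out["n_used"][j] = n_s
        if n_s <= p:
            out["status"][j] = "too_few_samples"
            n_skipped += 1
            continue
        g = gj[rows].astype(float)
        if g.var() < min_var:
            out["status"][j] = "monomorphic"
            n_skipped += 1
            continue
        e_r = ecols[rows]
        ge = g[:, None] * e_r
        if (ge.var(axis=0) < min_var).any():
            out["status"][j] = "constant_interaction"
            n_skipped += 1
            continue
        out["freq"][j] = g.mean() / 2.0

        if X.shape[0] != n_s:
            X = np.empty((n_s, p))
        X[:, 0] = 1.0
        X[:, 1] = g
        X[:, 2 : 2 + L] = e_r
        X[:, 2 + L : 2 + 2 * L] = ge
        if k:
            Cr = Cm[rows]
            X[:, 2 + 2 * L : 2 + 2 * L + k] = Cr
            X[:, 2 + 2 * L + k : 2 + 2 * L + 2 * k] = Cr * g[:, None]
            X[:, 2 + 2 * L + 2 * k :] = cov_env[rows]

        Yr = y2[rows]
        XtX = X.T @ X
        try:
            cf = cho_factor(XtX)
        except np.linalg.LinAlgError:
            out["status"][j] = "singular_design"
            n_skipped += 1
            continue
        inv_XtX = cho_solve(cf, np.eye(p))
        beta = cho_solve(cf, X.T @ Yr)  # p x r
        resid = Yr - X @ beta
        rss = np.einsum("ir,ir->r", resid, resid)
        dfres = n_s - p
        sigma2 = rss / dfres
        w_obs, c_hc = _robust_weights(robust_flavor, X, inv_XtX)
        A_J = inv_XtX[J_rel] @ X.T  # q x n_s
        E2 = resid**2  # n_s x r
        out["df"][j] = dfres if q == 1 else q

        if q == 1:
            jj = J_rel[0]
            a2w = A_J[0] ** 2 * (c_hc * w_obs)
            var_rob = a2w @ E2
            var_mod = sigma2 * inv_XtX[jj, jj]
            df_rob: float = dfres
            if robust_flavor == "BM":
                h = 1.0 - 1.0 / w_obs  # w = 1/(1-h) under BM
                df_rob = _bm_df(X, inv_XtX, h, int(jj))
            b = beta[jj]
            se_r = np.sqrt(var_rob)
            se_m = np.sqrt(var_mod)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_r = b / se_r
                t_m = b / se_m
            out["beta"][j] = b
            out["se_model"][j] = se_m
            out["se_robust"][j] = se_r
            out["stat_model"][j] = t_m
            out["stat_robust"][j] = t_r
            out["p_model"][j] = _p_from_t(t_m, dfres)
            out["p_robust"][j] = _p_from_t(t_r, df_rob)
        else:
            bJ = beta[J_rel]  # q x r
            sub_inv = inv_XtX[np.ix_(J_rel, J_rel)]
            E2w = E2 * (c_hc * w_obs)[:, None]
            V_rob = np.einsum("ln,nr,kn->rlk", A_J, E2w, A_J)
            w_m = np.empty(r)
            w_r = np.empty(r)
            sub_chol = np.linalg.cholesky(sub_inv)
            for t_i in range(r):
                b = bJ[:, t_i]
                z = np.linalg.solve(sub_chol, b)
                w_m[t_i] = (z @ z) / sigma2[t_i]
                try:
                    w_r[t_i] = b @ np.linalg.solve(V_rob[t_i], b)
                except np.linalg.LinAlgError:
                    w_r[t_i] = np.nan
            out["stat_model"][j] = w_m
            out["stat_robust"][j] = w_r
            out["p_model"][j] = np.clip(stats.chi2.sf(w_m, q), tiny, 1.0)
            out["p_robust"][j] = np.clip(stats.chi2.sf(w_r, q), tiny, 1.0)

    if m and n_skipped > 0.5 * m:
        raise RuntimeError(
            f"{n_skipped}/{m} SNPs skipped — inputs are probably misaligned"
        )
    if squeeze:
        for key in ("beta", "se_model", "se_robust", "stat_model", "stat_robust", "p_model", "p_robust"):
            out[key] = out[key][:, 0]
    return out


def run_gweis(
    G: GenotypeMatrix,
    E: EnvironmentVector,
    C: pd.DataFrame | np.ndarray | None,
    y: np.ndarray,
    robust_flavor: str = DEFAULT_FLAVOR,
    test: str = "interaction",
    reference_level: str | None = None,
    center_env: bool = True,
) -> pd.DataFrame:
    """Genome-wide interaction scan; one summary row per SNP.

    Emits both model-based and robust p-values (their divergence is the
    inflation diagnostic downstream).  Column names follow common GWAS
    summary-statistic conventions.
    """
    res = interaction_scan(
        G, E, C, y,
        robust_flavor=robust_flavor, test=test,
        reference_level=reference_level, center_env=center_env,
    )
    mk = G.markers
    return pd.DataFrame(
        {
            "SNP": mk["snp"],
            "CHR": mk["chrom"],
            "BP": mk["pos"],
            "A1": mk["a1"],
            "FREQ": res["freq"],
            "N": res["n_used"],
            "BETA": res["beta"],
            "SE": res["se_model"],
            "SE_ROBUST": res["se_robust"],
            "STAT": res["stat_model"],
            "STAT_ROBUST": res["stat_robust"],
            "DF": res["df"],
            "P": res["p_model"],
            "P_ROBUST": res["p_robust"],
            "STATUS": res["status"],
        }
    )
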