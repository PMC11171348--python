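"""Design matrices for the per-SNP linear interaction model.

The model regresses the phenotype on an intercept, the SNP allele count g,
the environment E (one column for a continuous exposure, levels−1
treatment-coded contrasts for farms), the g×E interaction(s) — the terms
of interest — and the covariates together with covariate×SNP and
covariate×environment interactions, which guard the interaction test
against confounded covariate interactions.

A continuous environment is centered before interaction columns are formed
(reduces collinearity; SNP main effects are then "at mean E").  Categorical
contrasts use the first level in sorted order as reference unless told
otherwise; interaction p-values are invariant to that choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import MISSING
from .simulate import EnvironmentVector

TERM_ORDER = ("intercept", "snp", "env", "snp_env", "covariates", "cov_snp", "cov_env")


class DegenerateDesignError(ValueError):
    """Environment constant or matrix rank-deficient after complete-case removal."""


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # n_used x p
    term_groups: dict[str, np.ndarray]  # term -> column indices
    rows_used: np.ndarray  # indices into the original sample order
    column_names: list[str]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def group(self, name: str) -> np.ndarray:
        return self.term_groups[name]


def environment_columns(
    E: EnvironmentVector,
    reference_level: str | None = None,
    center: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Numeric environment columns: n x 1 (continuous) or n x (levels−1)."""
    if E.kind == "continuous":
        v = E.values.astype(float)
        if center:
            v = v - v.mean()
        return v[:, None], ["env"]
    levels = list(E.levels)
    ref = reference_level if reference_level is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not among {levels}")
    others = [lv for lv in levels if lv != ref]
    vals = np.asarray([str(v) for v in E.values], dtype=object)
    cols = np.column_stack([(vals == lv).astype(float) for lv in others]) if others else np.zeros((len(vals), 0))
    return cols, [f"env[{lv}]" for lv in others]


def genotype_pca(G, n_components: int = 20) -> pd.DataFrame:
    """Top principal components of the centered-and-scaled genotype panel.

    Missing genotypes are mean-imputed (PCA only; the regression itself is
    complete-case).  Returned columns are orthonormal per-sample
    eigenvectors, eigenvalue-descending, each signed so its
    largest-magnitude entry is positive.
    """
    if n_components <= 0:
        if n_components == 0:
            return pd.DataFrame(index=range(G.n_samples))
        raise ValueError("n_components must be >= 0")
    n, m = G.genotypes.shape
    if n_components >= min(n, m):
        raise ValueError(f"n_components must be < min(n, m) = {min(n, m)}")
    X = G.genotypes.astype(float)
    miss = X == MISSING
    if miss.any():
        X[miss] = np.nan
        col_mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(col_mean, inds[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :n_components]
    for k in range(pcs.shape[1]):
        j = np.argmax(np.abs(pcs[:, k]))
        if pcs[j, k] < 0:
            pcs[:, k] = -pcs[:, k]
    return pd.DataFrame(pcs, columns=[f"PC{i + 1}" for i in range(n_components)])


def build_design(
    g: np.ndarray,
    E: EnvironmentVector,
    C: pd.DataFrame | np.ndarray | None,
    y: np.ndarray | None = None,
    reference_level: str | None = None,
    center_env: bool = True,
    check_rank: bool = True,
) -> DesignMatrix:
    """Assemble the full interaction design for one SNP.

    Rows with a missing genotype, environment, covariate or phenotype are
    removed (complete-case) and recorded in ``rows_used``.  Column count is
    2 + 2L + 2k + kL for k covariates and L environment columns.
    """
    g = np.asarray(g, dtype=float)
    n = len(g)
    if C is None:
        Cm = np.zeros((n, 0))
        cov_names: list[str] = []
    elif isinstance(C, pd.DataFrame):
        Cm = C.to_numpy(dtype=float)
        cov_names = [str(c) for c in C.columns]
    else:
        Cm = np.asarray(C, dtype=float)
        cov_names = [f"cov{i + 1}" for i in range(Cm.shape[1])]

    ecols_full, env_names = environment_columns(E, reference_level, center=center_env)
    if E.kind == "categorical":
        env_missing = pd.isna(pd.Series(list(E.values))).to_numpy()
    else:
        env_missing = ~np.isfinite(E.values.astype(float))

    keep = (g != MISSING) & np.isfinite(g) & ~env_missing
    if Cm.shape[1]:
        keep &= np.isfinite(Cm).all(axis=1)
    if y is not None:
        keep &= np.isfinite(np.asarray(y, dtype=float))
    rows_used = np.flatnonzero(keep)

    gv = g[rows_used]
    ecols = ecols_full[rows_used]
    Cv = Cm[rows_used]

    if E.kind == "continuous":
        if np.ptp(ecols) == 0:
            raise DegenerateDesignError("environment constant after complete-case removal")
    else:
        present = {str(v) for v in np.asarray(E.values, dtype=object)[rows_used]}
        if len(present) < 2:
            raise DegenerateDesignError("environment constant after complete-case removal")

    L = ecols.shape[1]
    k = Cv.shape[1]
    n_used = len(rows_used)

    blocks = [
        np.ones((n_used, 1)),
        gv[:, None],
        ecols,
        gv[:, None] * ecols,
        Cv,
        Cv * gv[:, None],
        np.hstack([Cv * ecols[:, l][:, None] for l in range(L)]) if (k and L) else np.zeros((n_used, k * L)),
    ]
    names = (
        ["intercept", "snp"]
        + env_names
        + [f"snp:{e}" for e in env_names]
        + cov_names
        + [f"{c}:snp" for c in cov_names]
        + [f"{c}:{e}" for l, e in enumerate(env_names) for c in cov_names]
    )
    X = np.hstack(blocks)
    sizes = [b.shape[1] for b in blocks]
    offsets = np.cumsum([0] + sizes)
    term_groups = {
        t: np.arange(offsets[i], offsets[i + 1]) for i, t in enumerate(TERM_ORDER)
    }

    if check_rank:
        _check_full_rank(X, names)
    return DesignMatrix(X, term_groups, rows_used, names)


def _check_full_rank(X: np.ndarray, names: list[str], tol_factor: float = 1e-9) -> None:
    # scale columns so the tolerance is meaningful for mixed-unit designs
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    from scipy.linalg import qr

    _, R, piv = qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * tol_factor if diag.size else 0.0
    bad = diag < tol
    if bad.any():
        culprits = [names[piv[i]] for i in np.flatnonzero(bad)]
        raise DegenerateDesignError(
            f"design matrix rank-deficient; collinear column(s): {culprits}"
        )
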