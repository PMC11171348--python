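"""Inflation diagnostics for genome-wide test statistics.

Three complementary views: QQ-plot tables of observed vs expected
−log10 p; the genomic inflation factor λ_GC (median χ² over the null
median 0.4549); and the LD score regression intercept, which separates
polygenic signal (slope on LD score) from confounding/miscalibration
(intercept above 1).  The comparison of intercepts for model-based vs
sandwich interaction statistics is the headline calibration check: under
heteroskedasticity the model-based intercept drifts upward while the
robust one stays near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["qq_table", "genomic_inflation", "ldsc_intercept", "LDSCFit", "chi2_from_p"]

CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


def chi2_from_p(p: np.ndarray, df: int = 1) -> np.ndarray:
    """Map two-sided p-values back to chi-square statistics."""
    p = np.clip(np.asarray(p, dtype=float), np.finfo(float).tiny, 1.0)
    return stats.chi2.isf(p, df)


def qq_table(p_values: np.ndarray) -> pd.DataFrame:
    """Observed (sorted) vs expected −log10 p under the uniform null."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any():
        warnings.warn("p-values at or below 0 clamped to machine minimum", stacklevel=2)
        p = np.clip(p, np.finfo(float).tiny, None)
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    obs = np.sort(p)
    m = len(obs)
    expected = np.arange(1, m + 1) / (m + 1.0)
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(obs)}
    )


def genomic_inflation(p_values: np.ndarray | None = None, chi2: np.ndarray | None = None) -> float:
    """λ_GC = median(χ²) / 0.4549."""
    if chi2 is None:
        if p_values is None:
            raise ValueError("supply p_values or chi2")
        chi2 = chi2_from_p(p_values)
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("no statistics")
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


@dataclass
class LDSCFit:
    intercept: float
    intercept_se: float
    slope: float
    n_snps: int
    n_blocks: int
    weighting: str = "1/max(l,1)"


def _wls(ell: np.ndarray, chi2: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    X = np.column_stack([np.ones_like(ell), ell])
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ chi2)
    return float(coef[0]), float(coef[1])


def ldsc_intercept(
    chi2: np.ndarray,
    ld: np.ndarray,
    n_samples: int | None = None,
    n_blocks: int = 50,
) -> LDSCFit:
    """LD score regression of χ² on LD score; intercept with jackknife SE.

    Weighted least squares with weights 1/max(ℓ, 1) (single-step; the
    iterative heteroskedasticity weighting of the reference software is not
    needed for an intercept-direction diagnostic).  The standard error
    comes from a leave-one-block-out jackknife over contiguous marker
    blocks.
    """
    chi2 = np.asarray(chi2, dtype=float)
    ell = np.asarray(ld, dtype=float)
    if chi2.shape != ell.shape:
        raise ValueError("chi2 and ld must align")
    m = len(chi2)
    if m <= n_blocks:
        raise ValueError(f"need more SNPs ({m}) than jackknife blocks ({n_blocks})")
    if np.ptp(ell) == 0:
        warnings.warn("constant LD scores: slope unidentifiable, intercept = weighted mean", stacklevel=2)
        w = 1.0 / np.maximum(ell, 1.0)
        icpt = float(np.average(chi2, weights=w))
        boundaries = np.linspace(0, m, n_blocks + 1, dtype=int)
        ests = []
        for b in range(n_blocks):
            mask = np.ones(m, dtype=bool)
            mask[boundaries[b] : boundaries[b + 1]] = False
            ests.append(np.average(chi2[mask], weights=w[mask]))
        ests = np.asarray(ests)
        se = float(np.sqrt((n_blocks - 1) / n_blocks * ((ests - ests.mean()) ** 2).sum()))
        return LDSCFit(icpt, se, 0.0, m, n_blocks)

    w = 1.0 / np.maximum(ell, 1.0)
    icpt, slope = _wls(ell, chi2, w)
    boundaries = np.linspace(0, m, n_blocks + 1, dtype=int)
    ests = np.empty(n_blocks)
    for b in range(n_blocks):
        mask = np.ones(m, dtype=bool)
        mask[boundaries[b] : boundaries[b + 1]] = False
        ests[b], _ = _wls(ell[mask], chi2[mask], w[mask])
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((ests - ests.mean()) ** 2).sum()))
    return LDSCFit(icpt, se, slope, m, n_blocks)
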