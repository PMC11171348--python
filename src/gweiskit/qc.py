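"""Marker and sample quality control.

Filter order (documented, deterministic): samples with excessive
missingness are dropped first; markers are then filtered in a single pass —
missing position, duplicate (chrom, pos), call rate, MAF, Hardy–Weinberg
exact test, and (when trios are supplied) Mendelian error rate.  Each
excluded marker is attributed to the first filter that removed it.
Frequencies and call rates are computed on non-missing genotypes after the
sample filter, all samples being treated as founders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeMatrix

FILTER_ORDER = ("position_missing", "duplicate", "call_rate", "maf", "hwe", "mendel")


class EmptyPanelError(RuntimeError):
    """Every marker was removed; the pipeline cannot proceed."""


@dataclass
class QCThresholds:
    maf: float = 0.05
    call_rate: float = 0.90
    hwe_p: float = 1e-6
    mendel_rate: float = 0.02
    sample_missing: float = 0.10


@dataclass
class QCReport:
    thresholds: QCThresholds
    sample_mask: np.ndarray  # True = kept
    snp_mask: np.ndarray  # True = kept
    exclusions: dict[str, int]  # per-filter counts, first-filter attribution
    n_samples_removed: int
    snp_filter: pd.DataFrame = field(repr=False)  # per-SNP attributed filter ('' = kept)

    def summary(self) -> dict:
        return {
            "thresholds": self.thresholds.__dict__,
            "n_samples_removed": self.n_samples_removed,
            "n_snps_removed": int((~self.snp_mask).sum()),
            "exclusions": dict(self.exclusions),
        }

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.snp_filter.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        prefix.with_suffix(".json").write_text(json.dumps(self.summary(), indent=2))


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy–Weinberg test p-value from genotype counts.

    The p-value sums the conditional probabilities (given allele counts) of
    all heterozygote counts no more probable than the observed one.
    Monomorphic markers return p = 1 by convention.
    """
    if min(n_hom1, n_het, n_hom2) < 0 or (n_hom1 + n_het + n_hom2) == 0:
        raise ValueError("genotype counts must be non-negative with a positive total")
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het  # rare-or-not does not matter; symmetric
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # heterozygote count has the parity of the rare allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    # unnormalized conditional probabilities via the stable midpoint recurrence
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h*(h-1) / ((rare-h+2)*(2n-rare-h+2))
    h = mid
    while h >= 2:
        r = (h * (h - 1)) / ((rare - h + 2.0) * (2 * n - rare - h + 2.0))
        probs[h - 2] = probs[h] * r
        h -= 2
    # upward recurrence: P(h+2)/P(h) = (rare-h)*(2n-rare-h) / ((h+2)*(h+1))
    h = mid
    while h + 2 <= rare:
        r = ((rare - h) * (2 * n - rare - h)) / ((h + 2.0) * (h + 1.0))
        probs[h + 2] = probs[h] * r
        h += 2
    total = sum(probs.values())
    obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_chi2_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """1-df chi-square Hardy–Weinberg test (offered as an alternative flavor)."""
    from scipy import stats

    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("empty genotype counts")
    p = (2 * n_hom1 + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(stat, 1))


def mendel_error_rate(G: GenotypeMatrix, trios: pd.DataFrame) -> np.ndarray:
    """Per-SNP Mendelian error rate over trios.

    A trio errs at a marker when the child's A1 count is impossible given
    the parents' (outside [#hom-A1 parents, 2 − #hom-A2 parents]).  The rate
    divides by trios with all three genotypes observed; markers with no
    complete trio get NaN (excluded from the filter).
    """
    idx = {s: i for i, s in enumerate(G.samples)}
    missing_members = [
        s for col in ("child", "father", "mother") for s in trios[col] if s not in idx
    ]
    if missing_members:
        raise ValueError(f"trio members absent from panel: {missing_members[:5]}")
    child = G.genotypes[[idx[s] for s in trios["child"]]].astype(np.int16)
    father = G.genotypes[[idx[s] for s in trios["father"]]].astype(np.int16)
    mother = G.genotypes[[idx[s] for s in trios["mother"]]].astype(np.int16)

    complete = (child != MISSING) & (father != MISSING) & (mother != MISSING)
    lo = (father == 2).astype(np.int16) + (mother == 2).astype(np.int16)
    hi = 2 - (father == 0).astype(np.int16) - (mother == 0).astype(np.int16)
    err = complete & ((child < lo) | (child > hi))
    denom = complete.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(denom > 0, err.sum(axis=0) / denom, np.nan)
    return rate


def apply_qc(
    G: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    trios: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample and marker filters; return the filtered panel and report.

    Idempotent: re-running on the filtered output removes nothing.
    """
    thr = thresholds or QCThresholds()
    n, m = G.genotypes.shape

    sample_mask = G.sample_missing_rate() <= thr.sample_missing
    n_samples_removed = int((~sample_mask).sum())
    Gs = G.subset(sample_idx=np.flatnonzero(sample_mask)) if n_samples_removed else G

    reason = np.full(m, "", dtype=object)

    pos = Gs.markers["pos"].to_numpy()
    bad_pos = ~(pos > 0)
    reason[bad_pos & (reason == "")] = "position_missing"

    dup = Gs.markers.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
    dup |= Gs.markers.duplicated(subset=["chrom", "pos"], keep="last").to_numpy()
    reason[dup & (reason == "")] = "duplicate"

    cr = Gs.call_rate()
    reason[(cr < thr.call_rate) & (reason == "")] = "call_rate"

    freq = Gs.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1 - freq)
    low_maf = ~(maf >= thr.maf)  # catches NaN (all-missing) too
    reason[low_maf & (reason == "")] = "maf"

    todo = np.flatnonzero(reason == "")
    geno = Gs.genotypes
    for j in todo:
        col = geno[:, j]
        obs = col[col != MISSING]
        p = hwe_exact_test(int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum()))
        if p < thr.hwe_p:
            reason[j] = "hwe"

    if trios is not None and len(trios):
        rate = mendel_error_rate(Gs, trios)
        bad = np.nan_to_num(rate, nan=0.0) > thr.mendel_rate
        reason[bad & (reason == "")] = "mendel"

    snp_mask = reason == ""
    if not snp_mask.any():
        raise EmptyPanelError("all markers removed by QC")

    exclusions = {f: int((reason == f).sum()) for f in FILTER_ORDER}
    snp_filter = pd.DataFrame(
        {"snp": Gs.markers["snp"], "chrom": Gs.markers["chrom"], "pos": Gs.markers["pos"], "filter": reason}
    )
    out = Gs.subset(snp_idx=np.flatnonzero(snp_mask))
    report = QCReport(
        thresholds=thr,
        sample_mask=sample_mask,
        snp_mask=snp_mask,
        exclusions=exclusions,
        n_samples_removed=n_samples_removed,
        snp_filter=snp_filter,
    )
    return out, report
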