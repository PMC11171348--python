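"""Readers and writers for the standard file formats the pipeline touches.

Genotypes travel as PLINK 1 binary triples (.bed/.bim/.fam, SNP-major,
2-bit encoded); per-sample metadata as a tab-separated table with a header;
gene positions as a 4-column tab-separated annotation (1-based, inclusive
on both ends); gene sets as GMT.

Genotype coding convention: the stored value is the count of the BIM A1
allele (0, 1, 2) with ``-1`` as the missing sentinel.  The effect allele is
recorded per SNP; all interaction tests downstream are invariant to an
allele flip (the beta changes sign, the p-value does not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1
#: autosome vocabulary for Bos taurus
AUTOSOMES = tuple(str(i) for i in range(1, 30))

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes (SNP-major, low bits = first sample):
#   00 -> homozygous A1 (A1 count 2)
#   01 -> missing
#   10 -> heterozygous  (A1 count 1)
#   11 -> homozygous A2 (A1 count 0)
_CODE_TO_GENO = np.array([2, MISSING, 1, 0], dtype=np.int8)
_GENO_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Malformed input file."""


class SchemaError(ValueError):
    """A table does not have the requested columns / keys."""


@dataclass
class GenotypeMatrix:
    """n x m additive-coded genotype panel with its marker map.

    ``genotypes[i, j]`` is the A1-allele count of sample ``i`` at marker
    ``j`` (0/1/2) or ``MISSING``.  ``markers`` has columns
    ``snp, chrom, pos, a1, a2`` (pos 1-based).
    """

    genotypes: np.ndarray
    samples: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x markers)")
        n, m = self.genotypes.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} sample IDs for {n} genotype rows")
        if m != len(self.markers):
            raise ValueError(f"{len(self.markers)} marker records for {m} genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        g = self.genotypes
        samples = self.samples
        markers = self.markers
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = g[sample_idx]
            samples = [self.samples[i] for i in np.flatnonzero(sample_idx)] \
                if sample_idx.dtype == bool else [self.samples[i] for i in sample_idx]
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            g = g[:, snp_idx]
            markers = markers.loc[markers.index[snp_idx]].reset_index(drop=True)
        return GenotypeMatrix(g.copy(), list(samples), markers.copy())

    def allele_freq(self) -> np.ndarray:
        """A1 allele frequency per marker over non-missing genotypes (NaN if all missing)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            freq = g.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(freq, dtype=float)

    def call_rate(self) -> np.ndarray:
        return 1.0 - (self.genotypes == MISSING).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)


def _markers_frame(snp, chrom, pos, a1, a2) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": np.asarray(snp, dtype=object),
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": np.asarray(a1, dtype=object),
            "a2": np.asarray(a2, dtype=object),
        }
    )


def write_plink(gm: GenotypeMatrix, prefix: str | Path, fam: pd.DataFrame | None = None) -> None:
    """Write a .bed/.bim/.fam triple (SNP-major 2-bit .bed)."""
    prefix = Path(prefix)
    n, m = gm.genotypes.shape
    # BIM: chrom, snp, cM, pos, a1, a2
    bim = pd.DataFrame(
        {
            "chrom": gm.markers["chrom"],
            "snp": gm.markers["snp"],
            "cm": 0,
            "pos": gm.markers["pos"],
            "a1": gm.markers["a1"],
            "a2": gm.markers["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    if fam is None:
        fam = pd.DataFrame(
            {
                "fid": gm.samples,
                "iid": gm.samples,
                "pat": 0,
                "mat": 0,
                "sex": 0,
                "pheno": -9,
            }
        )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n_bytes = (n + 3) // 4
    lut = np.zeros(256, dtype=np.uint8)
    for geno, code in _GENO_TO_CODE.items():
        lut[np.int8(geno).view(np.uint8)] = code
    # pad columns beyond n with genotype 0 (ignored on read)
    padded = np.zeros((m, 4 * n_bytes), dtype=np.int8)
    padded[:, :n] = gm.genotypes.T
    codes = lut[padded.view(np.uint8)]
    out = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def read_plink(prefix: str | Path, autosomes_only: bool = True) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triple into a :class:`GenotypeMatrix`.

    Only SNP-major mode is supported (the third magic byte must be 0x01).
    Non-autosomal markers (labels outside "1".."29") are rejected at load
    with a warning carrying the excluded count.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(p)

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str, "fid": str},
    )
    n = len(fam)
    m = len(bim)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC[:2]:
        raise FormatError(
            f"{bed_path}: bad magic bytes at offset 0 "
            f"(got {raw[:2].hex() if len(raw) >= 2 else raw.hex()}, want 6c1b)"
        )
    if raw[2] != 0x01:
        raise FormatError(f"{bed_path}: byte offset 2 is {raw[2]:#04x}; only SNP-major (0x01) supported")
    n_bytes = (n + 3) // 4
    expected = 3 + n_bytes * m
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: truncated or oversized .bed (have {len(raw)} bytes, "
            f"expected {expected} at byte offset {min(len(raw), expected)})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    # unpack 2-bit codes, low bits first
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = data & 0b11
    codes[:, 1::4] = (data >> 2) & 0b11
    codes[:, 2::4] = (data >> 4) & 0b11
    codes[:, 3::4] = (data >> 6) & 0b11
    geno = _CODE_TO_GENO[codes[:, :n]].T  # n x m

    markers = _markers_frame(bim["snp"], bim["chrom"], bim["pos"], bim["a1"], bim["a2"])
    gm = GenotypeMatrix(geno, list(fam["iid"]), markers)
    if autosomes_only:
        keep = markers["chrom"].isin(AUTOSOMES).to_numpy()
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} non-autosomal markers at load", stacklevel=2)
            gm = gm.subset(snp_idx=np.flatnonzero(keep))
    return gm


@dataclass
class SampleTable:
    """Phenotypes, covariates and environment per individual, keyed by IID."""

    table: pd.DataFrame
    phenotype_name: str
    covariate_names: list[str]
    environment_name: str

    @property
    def iids(self) -> list[str]:
        return list(self.table["IID"])

    def complete_mask(self) -> np.ndarray:
        """True where phenotype, environment and all covariates are present."""
        cols = [self.phenotype_name, self.environment_name, *self.covariate_names]
        return ~self.table[cols].isna().any(axis=1).to_numpy()

    def aligned_to(self, samples: Sequence[str]) -> "SampleTable":
        """Reorder rows to a genotype sample order (pure permutation/selection)."""
        idx = self.table.set_index("IID")
        missing = [s for s in samples if s not in idx.index]
        if missing:
            raise SchemaError(f"{len(missing)} genotyped samples absent from sample table: {missing[:5]}")
        out = idx.loc[list(samples)].reset_index()
        return replace(self, table=out)


def read_sample_table(
    path: str | Path,
    phenotype_name: str,
    covariate_names: Sequence[str],
    environment_name: str,
) -> SampleTable:
    """Read the per-sample TSV (header required, IID column required).

    Rows with missing phenotype/environment/covariates are kept and flagged
    through :meth:`SampleTable.complete_mask`, never silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    if "IID" not in df.columns:
        raise SchemaError(f"no IID column in {path}; columns: {list(df.columns)}")
    if df["IID"].duplicated().any():
        dups = df["IID"][df["IID"].duplicated()].tolist()
        raise SchemaError(f"duplicate IIDs in {path}: {dups[:5]}")
    wanted = [phenotype_name, environment_name, *covariate_names]
    absent = [c for c in wanted if c not in df.columns]
    if absent:
        raise SchemaError(f"columns {absent} not in {path}; available: {list(df.columns)}")
    return SampleTable(df, phenotype_name, list(covariate_names), environment_name)


@dataclass
class GeneAnnotation:
    """Gene windows: gene_id, chrom, start, stop (1-based, inclusive)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene_id", "chrom", "start", "stop"}
        if not need.issubset(self.table.columns):
            raise SchemaError(f"gene annotation needs columns {sorted(need)}")
        if (self.table["start"] > self.table["stop"]).any():
            bad = self.table.loc[self.table["start"] > self.table["stop"], "gene_id"].tolist()
            raise FormatError(f"gene start > stop for {bad[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """4-column tab-separated gene annotation: chrom, start, stop, gene_id."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "stop", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    return GeneAnnotation(df)


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.table[["chrom", "start", "stop", "gene_id"]].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GeneSetCollection:
    """set_id -> member gene ids; only sets usable for competitive analysis."""

    sets: dict[str, list[str]]
    n_input_sets: int = 0
    n_dropped: int = 0


def read_gene_sets(
    path: str | Path,
    annotation: GeneAnnotation | None = None,
    min_genes: int = 2,
) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, genes...).

    Sets are filtered to those with at least ``min_genes`` member genes
    present in ``annotation`` (competitive analysis needs multiple genes).
    """
    path = Path(path)
    known = set(annotation.gene_ids) if annotation is not None else None
    sets: dict[str, list[str]] = {}
    n_input = 0
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 2")
            name, _desc, *genes = fields
            n_input += 1
            if known is not None:
                genes = [g for g in genes if g in known]
            genes = list(dict.fromkeys(genes))
            if len(genes) >= min_genes:
                sets[name] = genes
            else:
                n_dropped += 1
    if n_input == 0:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets, n_input_sets=n_input, n_dropped=n_dropped)


def write_gene_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
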