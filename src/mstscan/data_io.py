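"""Genotype, phenotype and scan-result I/O.

Genotypes are read from PLINK 1.9 binary filesets (bed/bim/fam, SNP-major
layout) and streamed SNP by SNP: a genome-wide scan touches each SNP once,
and a dense samples x SNPs matrix for biobank-scale data would not fit in
memory.  Allele counts are always oriented to the minor allele, so that
``maf <= 0.5`` holds for every emitted SNP.

Phenotypes and covariates arrive as tab-separated tables keyed by sample ID;
scan output is a TSV with a fixed column order and log-scale-safe p-value
serialization (p-values down to ~1e-300 survive a round trip).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit PLINK codes, little-endian within each byte:
#   00 -> homozygous A1 (2 copies of A1), 01 -> missing,
#   10 -> heterozygous, 11 -> homozygous A2 (0 copies of A1)
_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])
_BYTE_LOOKUP = np.empty((256, 4))
for _b in range(256):
    for _j in range(4):
        _BYTE_LOOKUP[_b, _j] = _CODE_TO_COUNT[(_b >> (2 * _j)) & 0b11]

# strings treated as missing values in phenotype/covariate tables
_NA_STRINGS = {"", "NA", "N/A", "NaN", "nan", "."}


@dataclass
class GenotypeVector:
    """One SNP's minor-allele counts with metadata.

    ``counts`` is a float vector over {0, 1, 2, NaN}; NaN marks missing
    calls.  ``maf`` is the frequency of the counted (minor) allele over
    non-missing samples and ``L`` the number of distinct observed genotype
    groups (1, 2 or 3).
    """

    snp_id: str
    chrom: str
    bp: int
    a1: str
    a2: str
    counts: np.ndarray
    maf: float = field(init=False)
    L: int = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        obs = self.counts[~np.isnan(self.counts)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise DataError(f"{self.snp_id}: allele counts outside {{0,1,2}}")
        f = float(obs.sum() / (2 * obs.size)) if obs.size else float("nan")
        self.maf = min(f, 1.0 - f) if obs.size else float("nan")
        self.L = int(np.unique(obs).size)

    @property
    def n(self) -> int:
        return self.counts.size

    def minor_oriented(self) -> "GenotypeVector":
        """Return self with counts flipped so the counted allele is minor."""
        obs = self.counts[~np.isnan(self.counts)]
        if obs.size == 0:
            return self
        f = obs.sum() / (2 * obs.size)
        if f <= 0.5:
            return self
        return GenotypeVector(self.snp_id, self.chrom, self.bp,
                              self.a2, self.a1, 2.0 - self.counts)


@dataclass
class SampleTable:
    """Aligned phenotype/covariate table for n samples.

    ``Y`` (n x K traits) and ``X`` (n x p covariates) share the row order of
    ``sample_id``.  ``domain_labels`` maps each trait to its trait domain
    (e.g. "lipid"); a scan analyses one domain at a time.
    """

    sample_id: pd.Index
    Y: pd.DataFrame
    X: pd.DataFrame
    domain_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.Y) != len(self.sample_id) or len(self.X) != len(self.sample_id):
            raise DataError("Y/X row count does not match sample_id")
        if self.Y.shape[1] < 1:
            raise DataError("at least one trait column is required")
        for c in self.Y.columns:
            col = self.Y[c].dropna()
            if len(col) and float(col.std()) == 0.0:
                raise DataError(f"trait {c!r} is constant (zero variance)")

    @property
    def trait_names(self) -> list[str]:
        return list(self.Y.columns)

    def traits_in_domain(self, domain: str) -> list[str]:
        return [t for t in self.trait_names if self.domain_labels.get(t) == domain]


@dataclass
class ScanRecord:
    """Per-SNP row of the genome-scan output."""

    snp_id: str
    chrom: str
    bp: int
    maf: float
    n_used: int
    L: int
    mst_V: float = np.nan
    mst_F: float = np.nan
    mst_df1: float = np.nan
    mst_df2: float = np.nan
    mst_p: float = np.nan
    ust_F: dict[str, float] = field(default_factory=dict)
    ust_p: dict[str, float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PLINK binary filesets
# ---------------------------------------------------------------------------

def read_fam(path: Path | str) -> list[str]:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise DataError(f"{path}: fam file needs at least 2 columns")
    return fam[1].tolist()


def read_bim(path: Path | str) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                      names=["chrom", "snp_id", "cm", "bp", "a1", "a2"])
    if bim["snp_id"].duplicated().any():
        dup = bim.loc[bim["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise DataError(f"{path}: duplicate SNP id {dup!r}")
    bim["bp"] = bim["bp"].astype(int)
    return bim


def read_plink(prefix: Path | str) -> tuple[Iterator[GenotypeVector], list[str]]:
    """Stream a PLINK bed/bim/fam fileset as minor-allele GenotypeVectors.

    Returns ``(iterator over GenotypeVector in bim order, fam sample ids)``.
    Counts are recoded to the minor allele whenever the stored A1 allele is
    the major one; missing calls propagate as NaN.
    """
    prefix = Path(prefix)
    sample_ids = read_fam(prefix.with_suffix(".fam"))
    bim = read_bim(prefix.with_suffix(".bim"))
    n, m = len(sample_ids), len(bim)
    bed_path = prefix.with_suffix(".bed")
    nbytes = (n + 3) // 4
    expected = 3 + nbytes * m
    actual = bed_path.stat().st_size
    if actual != expected:
        raise DataError(f"{bed_path}: size {actual} != expected {expected} "
                        f"for {n} samples x {m} SNPs (fam/bim/bed mismatch)")

    def _iter() -> Iterator[GenotypeVector]:
        with open(bed_path, "rb") as fh:
            header = fh.read(3)
            if header[:2] != _BED_MAGIC:
                raise DataError(f"{bed_path}: bad magic bytes {header[:2]!r}")
            if header[2:3] != _BED_SNP_MAJOR:
                raise DataError(f"{bed_path}: only SNP-major bed files supported")
            for _, row in bim.iterrows():
                raw = np.frombuffer(fh.read(nbytes), dtype=np.uint8)
                counts = _BYTE_LOOKUP[raw].reshape(-1)[:n]
                gv = GenotypeVector(row.snp_id, row.chrom, int(row.bp),
                                    row.a1, row.a2, counts)
                yield gv.minor_oriented()

    return _iter(), sample_ids


def write_plink(prefix: Path | str, genotypes: Sequence[GenotypeVector],
                sample_ids: Sequence[str]) -> None:
    """Write a bed/bim/fam fileset (SNP-major); inverse of :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for g in genotypes:
            fh.write(f"{g.chrom}\t{g.snp_id}\t0\t{g.bp}\t{g.a1}\t{g.a2}\n")
    n = len(sample_ids)
    count_to_code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        for g in genotypes:
            if g.counts.size != n:
                raise DataError(f"{g.snp_id}: {g.counts.size} samples, fam has {n}")
            codes = [0b01 if np.isnan(c) else count_to_code[float(c)]
                     for c in g.counts]
            buf = bytearray((n + 3) // 4)
            for i, code in enumerate(codes):
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def _numeric_frame(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Coerce all non-ID columns to float; NA strings become NaN, anything
    else non-numeric is fatal with a row/column report."""
    out = {}
    for col in df.columns:
        raw = df[col]
        cleaned = raw.where(~raw.astype(str).str.strip().isin(_NA_STRINGS))
        num = pd.to_numeric(cleaned, errors="coerce")
        bad = num.isna() & cleaned.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"{path}: non-numeric value {raw.iloc[row]!r} "
                            f"in column {col!r}, row {row + 2} (1-based incl. header)")
        out[col] = num
    return pd.DataFrame(out, index=df.index)


def read_samples(pheno_path: Path | str, covar_path: Path | str | None,
                 id_col: str = "IID",
                 domain_labels: dict[str, str] | None = None) -> SampleTable:
    """Read phenotype and covariate TSVs and inner-join them on sample ID."""
    pheno = pd.read_csv(pheno_path, sep="\t", dtype=str)
    if id_col not in pheno.columns:
        raise DataError(f"{pheno_path}: id column {id_col!r} not found")
    if pheno[id_col].duplicated().any():
        raise DataError(f"{pheno_path}: duplicate sample IDs")
    pheno = pheno.set_index(id_col)
    Y = _numeric_frame(pheno, str(pheno_path))

    if covar_path is None:
        X = pd.DataFrame(index=Y.index)
    else:
        covar = pd.read_csv(covar_path, sep="\t", dtype=str)
        if id_col not in covar.columns:
            raise DataError(f"{covar_path}: id column {id_col!r} not found")
        if covar[id_col].duplicated().any():
            raise DataError(f"{covar_path}: duplicate sample IDs")
        covar = covar.set_index(id_col)
        X = _numeric_frame(covar, str(covar_path))
        common = Y.index.intersection(X.index)
        dropped = len(Y.index.union(X.index)) - len(common)
        if dropped:
            logger.warning("read_samples: %d sample(s) absent from one of the "
                           "two files were dropped by the inner join", dropped)
        Y, X = Y.loc[common], X.loc[common]

    return SampleTable(sample_id=Y.index, Y=Y, X=X,
                       domain_labels=dict(domain_labels or {}))


def align_to_fam(table: SampleTable, fam_ids: Sequence[str]) -> tuple[SampleTable, np.ndarray]:
    """Reorder a SampleTable to fam order; returns the table restricted to
    samples present in both, plus the fam-index of each retained sample."""
    fam_index = pd.Index(fam_ids)
    keep = [i for i, sid in enumerate(fam_ids) if sid in table.sample_id]
    ids = fam_index[keep]
    return (SampleTable(sample_id=ids, Y=table.Y.loc[ids], X=table.X.loc[ids],
                        domain_labels=table.domain_labels),
            np.asarray(keep))


# ---------------------------------------------------------------------------
# Scan results
# ---------------------------------------------------------------------------

def scan_columns(trait_names: Sequence[str]) -> list[str]:
    cols = ["snp_id", "chrom", "bp", "maf", "n_used", "L",
            "mst_V", "mst_F", "mst_df1", "mst_df2", "mst_p"]
    for t in trait_names:
        cols += [f"ust_F_{t}", f"ust_p_{t}"]
    return cols


def records_to_frame(records: Iterable[ScanRecord],
                     trait_names: Sequence[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"snp_id": r.snp_id, "chrom": r.chrom, "bp": r.bp, "maf": r.maf,
               "n_used": r.n_used, "L": r.L, "mst_V": r.mst_V, "mst_F": r.mst_F,
               "mst_df1": r.mst_df1, "mst_df2": r.mst_df2, "mst_p": r.mst_p}
        for t in trait_names:
            row[f"ust_F_{t}"] = r.ust_F.get(t, np.nan)
            row[f"ust_p_{t}"] = r.ust_p.get(t, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=scan_columns(trait_names))


def write_scan(records: Iterable[ScanRecord], out: Path | str,
               trait_names: Sequence[str]) -> pd.DataFrame:
    """Serialize scan records as TSV.

    p-values and statistics are written in scientific notation with 6
    significant digits so that magnitudes like 1e-215 survive (double
    precision carries them; only the fixed-notation printf would not).
    """
    df = records_to_frame(records, trait_names)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, sep="\t", index=False, float_format="%.6e")
    return df


def read_scan(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Fixture generation (synthetic, for tests and the CLI smoke pipeline)
# ---------------------------------------------------------------------------

def make_fixture_dataset(out_dir: Path | str, n: int = 500, n_snps: int = 50,
                         k: int = 3, seed: int = 0,
                         missing_rate: float = 0.0) -> dict[str, Path]:
    """Write a small synthetic bed/bim/fam + pheno/covar TSV set.

    Genotypes are Hardy-Weinberg draws at MAFs uniform in [0.01, 0.5);
    traits are correlated Gaussians with genotype main effects on the first
    SNP, so a scan over the fixture has realistic (mostly null) structure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    genotypes = []
    for j in range(n_snps):
        maf = rng.uniform(0.01, 0.5)
        counts = rng.binomial(2, maf, size=n).astype(float)
        if missing_rate > 0:
            counts[rng.random(n) < missing_rate] = np.nan
        genotypes.append(GenotypeVector(f"snp{j:04d}", "1", 1000 * (j + 1),
                                        "A", "C", counts))
    prefix = out_dir / "fixture"
    write_plink(prefix, genotypes, sample_ids)

    rho = 0.3
    cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    eps = rng.multivariate_normal(np.zeros(k), cov, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(30, 70, size=n)
    g0 = np.nan_to_num(genotypes[0].counts)
    Y = 0.2 * g0[:, None] + 0.1 * sex[:, None] + 0.01 * age[:, None] + eps
    pheno = pd.DataFrame(Y, columns=[f"trait{j + 1}" for j in range(k)])
    pheno.insert(0, "IID", sample_ids)
    covar = pd.DataFrame({"IID": sample_ids, "SEX": sex, "AGE": age})
    pheno_path = out_dir / "pheno.tsv"
    covar_path = out_dir / "covar.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)
    covar.to_csv(covar_path, sep="\t", index=False)
    return {"prefix": prefix, "pheno": pheno_path, "covar": covar_path}
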