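"""Genome-wide scan driver and post-processing.

Per SNP: apply the MAF filter, refit the per-trait mean model (genotype
dummies + covariates), form the dispersion matrix and run the MST (and
optionally per-trait USTs).  Post-processing covers Bonferroni thresholds,
the two-stage ad hoc UST, replication filtering and greedy LD clumping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .data_io import GenotypeVector, SampleTable, ScanRecord
from .errors import MstScanError, UntestableSNPError
from .preprocess import dispersion, residualize
from .scale_tests import genotype_dummies, mst, ust, ust_from_sscp

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Scan-wide settings; all multiplicity thresholds are derived on demand
    so they can never go stale when M or the discovery count changes."""

    maf_min: float = 0.05
    alpha: float = 0.05
    n_domains: int = 8
    n_traits_total: int = 29
    min_group_n: int = 1
    clump_r2: float = 0.01
    clump_window_bp: int = 1_000_000

    def mst_threshold(self, M: int) -> float:
        return bonferroni_threshold(self.alpha, M * self.n_domains)

    def ust_threshold(self, M: int) -> float:
        return bonferroni_threshold(self.alpha, M * self.n_traits_total)

    def adhoc_threshold(self, M1: int) -> float:
        return bonferroni_threshold(self.alpha, M1)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance level alpha split over n_tests tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _testable(g: GenotypeVector, mask: np.ndarray, min_group_n: int) -> np.ndarray | None:
    """Return complete-case genotype values, or None if untestable."""
    gv = g.counts[mask]
    levels, counts = np.unique(gv, return_counts=True)
    keep_levels = levels[counts >= min_group_n]
    if keep_levels.size < 2:
        return None
    if keep_levels.size < levels.size:
        gv = gv.copy()
        gv[~np.isin(gv, keep_levels)] = np.nan
    return gv


def run_mst_scan(genotypes: Iterable[GenotypeVector], samples: SampleTable,
                 traits: Sequence[str] | None = None,
                 config: ScanConfig | None = None,
                 with_ust: bool = False) -> Iterator[ScanRecord]:
    """Stream ScanRecords for every SNP passing the MAF/testability filters.

    Assumes preprocessing (outlier removal) already happened on ``samples``.
    Per-SNP numerical failures are logged and emitted with missing p-values;
    they never abort the scan.
    """
    config = config or ScanConfig()
    traits = list(traits) if traits else samples.trait_names
    Y = samples.Y[traits].to_numpy(dtype=float)
    X = samples.X.to_numpy(dtype=float) if samples.X.shape[1] else None
    base_ok = ~np.isnan(Y).any(axis=1)
    if X is not None:
        base_ok &= ~np.isnan(X).any(axis=1)

    for g in genotypes:
        if not np.isfinite(g.maf) or g.maf < config.maf_min:
            continue
        mask = base_ok & ~np.isnan(g.counts)
        gv = _testable(g, mask, config.min_group_n)
        if gv is None:
            logger.info("skip %s: monomorphic in analysed samples", g.snp_id)
            continue
        used = mask.copy()
        used[mask] = ~np.isnan(gv)
        gv = gv[~np.isnan(gv)]
        n_used = int(used.sum())
        record = ScanRecord(snp_id=g.snp_id, chrom=g.chrom, bp=g.bp,
                            maf=g.maf, n_used=n_used, L=0)
        try:
            dummies, L = genotype_dummies(gv)
            record.L = L
            R = residualize(Y[used], dummies,
                            X[used] if X is not None else None, traits)
            D = dispersion(R)
            res = mst(D, dummies, L, n_used)
            record.mst_V, record.mst_F = res.V, res.F
            record.mst_df1, record.mst_df2 = res.df1, res.df2
            record.mst_p = res.p
            if with_ust:
                for t, u in zip(traits, ust_from_sscp(res)):
                    record.ust_F[t], record.ust_p[t] = u.F, u.p
        except UntestableSNPError:
            logger.info("skip %s: untestable", g.snp_id)
            continue
        except MstScanError as exc:
            logger.warning("%s: %s; emitted with missing p", g.snp_id, exc)
        yield record


def adhoc_ust(record: ScanRecord, D, dummies: np.ndarray, M1: int,
              mst_threshold: float, alpha: float = 0.05) -> dict[str, bool]:
    """Stage-2 trait attribution for a stage-1 (MST) hit.

    Runs the UST for every trait in the record's domain and flags trait k
    iff the SNP passed stage 1 AND ust_p[k] < alpha / M1.  A SNP that fails
    stage 1 gets no flags regardless of its USTs.
    """
    Dm = D.D if hasattr(D, "D") else np.asarray(D)
    names = D.trait_names if hasattr(D, "trait_names") else [
        f"trait{k+1}" for k in range(Dm.shape[1])]
    if not (record.mst_p < mst_threshold):
        record.flags = {t: False for t in names}
        return record.flags
    thr = bonferroni_threshold(alpha, M1)
    L = record.L
    for k, t in enumerate(names):
        u = ust(Dm[:, k], dummies, L, record.n_used, trait_index=k)
        record.ust_F[t], record.ust_p[t] = u.F, u.p
        record.flags[t] = bool(u.p < thr)
    return record.flags


def replication_filter(discovery: Sequence[ScanRecord],
                       replication: Sequence[ScanRecord],
                       alpha: float = 0.05) -> list[ScanRecord]:
    """Keep discovery hits whose replication MST p < alpha / (#discovery hits)."""
    if not discovery:
        return []
    threshold = bonferroni_threshold(alpha, len(discovery))
    rep_p = {r.snp_id: r.mst_p for r in replication}
    kept = []
    for rec in discovery:
        if rec.snp_id not in rep_p:
            logger.warning("replication_filter: %s absent from replication "
                           "scan; dropped", rec.snp_id)
            continue
        if rep_p[rec.snp_id] < threshold:
            kept.append(rec)
    return kept


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of allele counts over complete pairs."""
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def greedy_clump(records: Sequence[ScanRecord],
                 genotype_of: Callable[[str], np.ndarray],
                 r2_max: float = 0.01,
                 window_bp: int = 1_000_000) -> list[ScanRecord]:
    """Greedy LD clumping: repeatedly promote the smallest-p remaining record
    to index SNP and drop same-chromosome records within ``window_bp`` whose
    allele-count r^2 with it exceeds ``r2_max``.  Ties in p break by bp."""
    pool = sorted(records, key=lambda r: (r.mst_p, r.bp))
    kept: list[ScanRecord] = []
    while pool:
        index = pool.pop(0)
        kept.append(index)
        g_index = genotype_of(index.snp_id)
        survivors = []
        for rec in pool:
            if rec.chrom == index.chrom and abs(rec.bp - index.bp) <= window_bp:
                if _pearson_r2(g_index, genotype_of(rec.snp_id)) > r2_max:
                    continue
            survivors.append(rec)
        pool = survivors
    return kept
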