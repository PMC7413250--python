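"""Marker retention rules and per-locus summary statistics.

Implements the QC chain applied to panel SNP data before distance
computation: per-locus summaries (MAF, observed/expected heterozygosity,
PIC, Hardy–Weinberg goodness of fit, call rate), hard filters on MAF and
missingness, and plink-style sliding-window LD pruning on squared dosage
correlation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["snp_summary", "filter_variants", "ld_prune", "QCError"]


class QCError(ValueError):
    pass


def snp_summary(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus summary statistics over non-missing calls.

    Returns a DataFrame indexed by locus ID with columns ``maf``, ``ho``
    (observed heterozygosity), ``he`` (2pq), ``pic`` (Botstein biallelic
    form, 1 - p^2 - q^2 - 2 p^2 q^2), ``hwe_p`` (continuity-corrected 1-df
    chi-square goodness of fit to p^2 : 2pq : q^2; 1.0 for monomorphic
    loci), ``call_rate`` and ``missing_rate``.  Loci with zero non-missing
    calls get NaN summaries and are flagged in ``defined``.
    """
    d = gm.dosage
    called = d != MISSING
    n_called = called.sum(axis=0).astype(float)
    n0 = ((d == 0) & called).sum(axis=0).astype(float)
    n1 = (d == 1).sum(axis=0).astype(float)
    n2 = (d == 2).sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2.0 * n2) / (2.0 * n_called)  # ALT allele frequency
        q = 1.0 - p
        maf = np.minimum(p, q)
        ho = n1 / n_called
        he = 2.0 * p * q
        pic = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2

        exp0, exp1, exp2 = q**2 * n_called, he * n_called, p**2 * n_called
        chi2 = np.zeros(gm.n_loci)
        for obs, exp in ((n0, exp0), (n1, exp1), (n2, exp2)):
            term = np.maximum(np.abs(obs - exp) - 0.5, 0.0) ** 2
            chi2 += np.where(exp > 0, term / np.where(exp > 0, exp, 1.0), 0.0)
        hwe_p = stats.chi2.sf(chi2, df=1)
        hwe_p = np.where(maf == 0, 1.0, hwe_p)  # monomorphic: trivially in HWE

    defined = n_called > 0
    if not defined.all():
        logger.warning("%d loci have zero non-missing calls", int((~defined).sum()))
    out = pd.DataFrame({
        "maf": maf, "ho": ho, "he": he, "pic": pic, "hwe_p": hwe_p,
        "call_rate": n_called / gm.n_accessions,
        "missing_rate": 1.0 - n_called / gm.n_accessions,
        "defined": defined,
    }, index=pd.Index(gm.locus_ids, name="locus"))
    out.loc[~defined, ["maf", "ho", "he", "pic", "hwe_p"]] = np.nan
    return out


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    dropped_maf: int
    dropped_missing: int
    dropped_undefined: int


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.1,
    max_missing: float = 0.0,
    biallelic_only: bool = True,  # upstream parsing already guarantees this
) -> tuple[GenotypeMatrix, FilterReport]:
    """Retain loci with MAF strictly above ``maf_min`` (the threshold is a
    strict inequality) and missing fraction at most ``max_missing``."""
    summ = snp_summary(gm)
    defined = summ["defined"].to_numpy()
    pass_maf = np.where(defined, summ["maf"].to_numpy() > maf_min, False)
    pass_miss = summ["missing_rate"].to_numpy() <= max_missing
    keep = defined & pass_maf & pass_miss
    report = FilterReport(
        n_input=gm.n_loci,
        n_retained=int(keep.sum()),
        dropped_maf=int((defined & ~pass_maf).sum()),
        dropped_missing=int((defined & pass_maf & ~pass_miss).sum()),
        dropped_undefined=int((~defined).sum()),
    )
    if not keep.any():
        raise QCError(
            f"all {gm.n_loci} loci dropped (maf_min={maf_min}, max_missing={max_missing})"
        )
    return gm.take_loci(np.flatnonzero(keep)), report


def _window_r2(dosage: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns, pairwise-complete
    over non-missing calls."""
    df = pd.DataFrame(np.where(dosage == MISSING, np.nan, dosage.astype(float)))
    r = df.corr(min_periods=2).to_numpy()
    r2 = r**2
    np.fill_diagonal(r2, 0.0)
    return np.nan_to_num(r2, nan=0.0)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> tuple[GenotypeMatrix, int]:
    """Sliding-window LD pruning on squared dosage correlation.

    Windows of ``window_snps`` currently-kept loci advance by ``step_snps``
    along each chromosome; within a window, while any kept pair exceeds
    ``r2_max``, the pair earliest in locus order is resolved by removing its
    lower-MAF member (tie: the later locus).  Sweeps repeat until a full
    pass removes nothing, so no window of the pruned output contains an
    offending pair.  Deterministic given the input order.  Returns
    (pruned matrix, number of loci removed).
    """
    if window_snps < 2 or step_snps < 1:
        raise ValueError("window_snps must be >= 2 and step_snps >= 1")
    if not gm.is_position_sorted():
        raise QCError("loci are not sorted by chromosome and position; "
                      "call GenotypeMatrix.sorted_by_position() first")
    maf = snp_summary(gm)["maf"].to_numpy()
    keep = np.ones(gm.n_loci, dtype=bool)

    if gm.locus_meta is not None:
        chroms = gm.locus_meta["chrom"].astype(str).to_numpy()
    else:
        chroms = np.full(gm.n_loci, "1")

    for chrom in pd.unique(chroms):
        chrom_idx = np.flatnonzero(chroms == chrom)
        changed = True
        while changed:
            changed = False
            idx = chrom_idx[keep[chrom_idx]]
            for start in range(0, max(len(idx), 1), step_snps):
                active = idx[start:start + window_snps]
                active = active[keep[active]]
                if len(active) >= 2:
                    r2 = _window_r2(gm.dosage[:, active])
                    alive = np.ones(len(active), dtype=bool)
                    while True:
                        offender = None
                        for a in range(len(active)):
                            if not alive[a]:
                                continue
                            for b in range(a + 1, len(active)):
                                if alive[b] and r2[a, b] > r2_max:
                                    offender = (a, b)
                                    break
                            if offender:
                                break
                        if offender is None:
                            break
                        a, b = offender
                        drop = b if maf[active[b]] <= maf[active[a]] else a
                        alive[drop] = False
                        keep[active[drop]] = False
                        changed = True
                if start + window_snps >= len(idx):
                    break
    n_removed = int((~keep).sum())
    logger.info("ld_prune removed %d of %d loci", n_removed, gm.n_loci)
    return gm.take_loci(np.flatnonzero(keep)), n_removed
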