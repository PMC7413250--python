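"""Diversity indices, Weir–Cockerham Fst and the Mantel permutation test.

``diversity_indices`` is defined on any nonnegative abundance vector: with
p_i the normalized positive entries and S their count,

    Shannon–Wiener  H' = -sum p_i ln p_i          (nats)
    inverse Simpson H_B = 1 / sum p_i^2           (effective count)
    Simpson         lambda = 1 - sum p_i^2
    Pielou evenness J = H' / ln S                 (undefined for S = 1)

The Weir–Cockerham fixation-index estimator decomposes per-locus allelic
variance into among-population (a), among-individual-within-population (b)
and within-individual (c) components from genotype counts; the multi-locus
estimate is the ratio of sums, sum(a) / sum(a + b + c).

The Mantel test correlates the strict upper triangles of two labelled
distance matrices and builds its null by simultaneously permuting the rows
and columns of the second; the p-value uses the add-one rule
(1 + #{permuted >= observed}) / (n_permutations + 1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import MISSING, DistanceMatrix, GenotypeMatrix

__all__ = [
    "DiversityIndices", "diversity_indices",
    "weir_cockerham_fst", "FstResult",
    "mantel", "MantelResult",
]


@dataclass
class DiversityIndices:
    shannon: float
    inverse_simpson: float
    simpson_lambda: float
    pielou: float  # NaN when only one category is present
    richness: int


def diversity_indices(abundance: np.ndarray | list) -> DiversityIndices:
    """Closed-form diversity indices of a nonnegative abundance vector."""
    a = np.asarray(abundance, dtype=float)
    if a.ndim != 1 or len(a) == 0:
        raise ValueError("abundance must be a non-empty 1-D vector")
    if (a < 0).any() or not np.isfinite(a).all():
        raise ValueError("abundance entries must be finite and nonnegative")
    a = a[a > 0]
    if len(a) == 0:
        raise ValueError("abundance vector has no positive entries")
    p = a / a.sum()
    shannon = float(-(p * np.log(p)).sum())
    sum_p2 = float((p**2).sum())
    S = len(p)
    pielou = shannon / math.log(S) if S > 1 else float("nan")
    return DiversityIndices(
        shannon=shannon,
        inverse_simpson=1.0 / sum_p2,
        simpson_lambda=1.0 - sum_p2,
        pielou=pielou,
        richness=S,
    )


@dataclass
class FstResult:
    fst: float                    # multi-locus ratio-of-sums estimate
    per_locus: pd.DataFrame       # columns a, b, c, fst (NaN where undefined)
    n_loci_used: int


def weir_cockerham_fst(gm: GenotypeMatrix, groups: np.ndarray | list) -> FstResult:
    """Multi-locus Weir–Cockerham theta from dosages and group labels.

    Per locus, with r populations of (locus-wise non-missing) sizes n_i,
    ALT frequencies p_i and observed heterozygote fractions h_i:

        nbar = mean n_i,  nc = (r*nbar - sum n_i^2/(r*nbar)) / (r-1)
        pbar = weighted mean p_i,  s2 = sum n_i (p_i-pbar)^2 / ((r-1) nbar)
        hbar = weighted mean h_i

        a = nbar/nc [s2 - (pbar(1-pbar) - (r-1)/r s2 - hbar/4) / (nbar-1)]
        b = nbar/(nbar-1) [pbar(1-pbar) - (r-1)/r s2 - (2nbar-1)/(4nbar) hbar]
        c = hbar/2

    Loci with fewer than two populations of >= 2 genotyped individuals, or
    with zero total variance, are skipped.
    """
    groups = np.asarray(groups)
    if len(groups) != gm.n_accessions:
        raise ValueError("groups length must match n_accessions")
    pops = np.unique(groups)
    r = len(pops)
    if r < 2:
        raise ValueError("Fst needs at least two groups")

    d = gm.dosage
    called = d != MISSING
    # per population x locus counts
    n_i = np.stack([called[groups == g].sum(axis=0) for g in pops]).astype(float)
    alt = np.stack([np.where(called[groups == g], d[groups == g], 0).sum(axis=0) for g in pops])
    het = np.stack([((d[groups == g] == 1)).sum(axis=0) for g in pops]).astype(float)

    ok_pop = n_i >= 2
    usable = ok_pop.sum(axis=0) >= 2

    with np.errstate(invalid="ignore", divide="ignore"):
        # restrict every locus to its populations with >= 2 individuals
        n_eff = np.where(ok_pop, n_i, 0.0)
        r_eff = ok_pop.sum(axis=0).astype(float)
        n_tot = n_eff.sum(axis=0)
        nbar = n_tot / r_eff
        nc = (n_tot - (n_eff**2).sum(axis=0) / n_tot) / (r_eff - 1.0)
        p_i = np.where(ok_pop, alt / (2.0 * np.where(ok_pop, n_i, 1.0)), 0.0)
        h_i = np.where(ok_pop, het / np.where(ok_pop, n_i, 1.0), 0.0)
        pbar = (n_eff * p_i).sum(axis=0) / n_tot
        s2 = (n_eff * (p_i - pbar) ** 2).sum(axis=0) / ((r_eff - 1.0) * nbar)
        hbar = (n_eff * h_i).sum(axis=0) / n_tot

        inner = pbar * (1.0 - pbar) - (r_eff - 1.0) / r_eff * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    total = a + b + c
    use = usable & np.isfinite(total) & (total != 0)
    if not use.any():
        raise ValueError("no usable loci for Fst (all monomorphic or undersampled)")
    fst = float(a[use].sum() / total[use].sum())
    per_locus = pd.DataFrame({
        "a": np.where(use, a, np.nan),
        "b": np.where(use, b, np.nan),
        "c": np.where(use, c, np.nan),
        "fst": np.where(use, a / np.where(use, total, 1.0), np.nan),
    }, index=pd.Index(gm.locus_ids, name="locus"))
    return FstResult(fst=fst, per_locus=per_locus, n_loci_used=int(use.sum()))


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    alternative: str


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_permutations: int = 9999,
    alternative: str = "greater",
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    ``alternative`` is ``greater`` (default, upper tail on r), ``less`` or
    ``two-sided`` (tail on \\|r\\|).  The permutation stream must be seeded
    for reproducibility.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if dm1.n < 4:
        raise ValueError("Mantel test needs at least 4 items")
    dm2 = dm2.reorder(dm1.labels)
    n = dm1.n
    iu = np.triu_indices(n, k=1)
    x = dm1.values[iu]
    if x.std() == 0:
        raise ValueError("zero variance in first matrix's distances")
    if dm2.values[iu].std() == 0:
        raise ValueError("zero variance in second matrix's distances")

    xs = (x - x.mean()) / x.std()
    B = dm2.values

    def corr_with(perm: np.ndarray) -> float:
        y = B[np.ix_(perm, perm)][iu]
        ys = (y - y.mean()) / y.std()
        return float((xs * ys).mean())

    r_obs = corr_with(np.arange(n))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        r_p = corr_with(rng.permutation(n))
        if alternative == "greater":
            exceed += r_p >= r_obs
        elif alternative == "less":
            exceed += r_p <= r_obs
        else:
            exceed += abs(r_p) >= abs(r_obs)
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_permutations,
                        alternative=alternative)
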