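"""Phenotypic and genotypic dissimilarity matrices.

Phenotypic measures (on the trait table): Gower's coefficient for
mixed-type traits, and Euclidean / Manhattan / Mahalanobis on the numeric
(quantitative + ordinal-rank) traits.  Genotypic measures (on ALT-dosage
SNP matrices): identity-by-state allele sharing, Nei's standard genetic
distance between individuals treated as two-allele populations, Jaccard on
dosage vectors, and the modified Rogers distance.  A combined matrix fuses
one phenotypic and one genotypic view after rescaling each to [0, 1].

Conventions:

* Gower: d_G(i,j) = sum_c w_ijc d_ijc / sum_c w_ijc with per-trait
  d in [0,1] (range-scaled absolute difference for quantitative/ordinal,
  0/1 mismatch for nominal) and w_ijc = 0 when either value is missing or
  the trait has zero range.
* IBS: per-locus shared-allele count s = 2 - |g_i - g_j| (identical
  genotypes, including het-het, share 2; opposite homozygotes 0; het vs
  homozygote 1); similarity = mean s / 2; distance = 1 - similarity.
* Nei: individual allele frequency x = dosage/2; D = -ln(Jxy / sqrt(Jx Jy))
  with J the mean over loci of the allele-frequency cross/within products.
  Profiles sharing no alleles give +inf, flagged on the matrix.
* Jaccard: d = 1 - sum(PQ) / (sum P^2 + sum Q^2 - sum(PQ)) on dosages.
* Modified Rogers: d_R = (1/m) sum_l sqrt(0.5 sum_alleles (p - q)^2); for
  biallelic dosages the per-locus term reduces to |g_i - g_j| / 2.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .formats_io import MISSING, DistanceMatrix, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "gower", "euclidean", "manhattan", "mahalanobis",
    "ibs_distance", "nei_distance", "jaccard_distance", "rogers_distance",
    "combine_matrices",
    "PHENO_MEASURES", "GENO_MEASURES",
]


# ---------------------------------------------------------------------------
# phenotypic measures
# ---------------------------------------------------------------------------

def gower(pheno: PhenotypeTable) -> DistanceMatrix:
    """Gower mixed-type dissimilarity over all declared traits."""
    if not pheno.trait_ids:
        raise ValueError("phenotype table has no traits")
    n = len(pheno.accession_ids)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for trait in pheno.trait_ids:
        kind = pheno.trait_kinds[trait]
        col = pheno.data[trait]
        if kind == "nominal":
            codes = col.cat.codes.to_numpy().astype(float)  # -1 = missing
            present = codes >= 0
            d = (codes[:, None] != codes[None, :]).astype(float)
        else:
            x = col.to_numpy(dtype=float)
            present = ~np.isnan(x)
            vals = x[present]
            rng = vals.max() - vals.min() if present.any() else 0.0
            if rng == 0:
                continue  # zero-range trait: weight 0 for every pair
            xs = np.where(present, x, 0.0)
            d = np.abs(xs[:, None] - xs[None, :]) / rng
        w = (present[:, None] & present[None, :]).astype(float)
        num += w * np.nan_to_num(d, nan=0.0)
        den += w
    off = ~np.eye(n, dtype=bool)
    if (den[off] == 0).any():
        i, j = np.argwhere((den == 0) & off)[0]
        raise ValueError(
            f"Gower distance undefined for pair "
            f"({pheno.accession_ids[i]!r}, {pheno.accession_ids[j]!r}): no shared traits"
        )
    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(pheno.accession_ids, values)


def _numeric_traits(pheno: PhenotypeTable, standardize: bool) -> np.ndarray:
    nominal = pheno.kinds_of(("nominal",))
    if nominal:
        raise ValueError(
            f"nominal traits {nominal} cannot enter this metric; use gower() instead"
        )
    X = pheno.numeric_matrix()
    if np.isnan(X).any():
        raise ValueError("missing trait values present; impute or use gower()")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            const = [t for t, s in zip(pheno.trait_ids, sd) if s == 0]
            raise ValueError(f"constant traits cannot be standardized: {const}")
        X = (X - X.mean(axis=0)) / sd
    return X


def euclidean(pheno: PhenotypeTable, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance on (by default standardized) numeric traits."""
    X = _numeric_traits(pheno, standardize)
    return DistanceMatrix.from_condensed(pheno.accession_ids, pdist(X, "euclidean"))


def manhattan(pheno: PhenotypeTable, standardize: bool = True) -> DistanceMatrix:
    """Manhattan (city-block) distance on numeric traits."""
    X = _numeric_traits(pheno, standardize)
    return DistanceMatrix.from_condensed(pheno.accession_ids, pdist(X, "cityblock"))


def mahalanobis(pheno: PhenotypeTable, pseudo_inverse: bool = False) -> DistanceMatrix:
    """Mahalanobis distance using the sample covariance of the trait table.

    Singular covariance raises unless ``pseudo_inverse=True`` (then the
    Moore–Penrose inverse is used, with a logged warning).
    """
    X = _numeric_traits(pheno, standardize=False)
    n, p = X.shape
    S = np.cov(X, rowvar=False)
    if not pseudo_inverse:
        if n <= p:
            raise ValueError(
                f"sample covariance is singular with {n} accessions <= {p} traits; "
                "enable pseudo_inverse"
            )
        try:
            VI = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular covariance matrix; enable pseudo_inverse") from exc
        if not np.isfinite(VI).all() or np.linalg.cond(S) > 1e12:
            raise ValueError("near-singular covariance matrix; enable pseudo_inverse")
    else:
        VI = np.linalg.pinv(S)
        logger.warning("mahalanobis: using pseudo-inverse of a (near-)singular covariance")
    return DistanceMatrix.from_condensed(
        pheno.accession_ids, pdist(X, "mahalanobis", VI=VI)
    )


# ---------------------------------------------------------------------------
# genotypic measures
# ---------------------------------------------------------------------------

def _complete_dosage(gm: GenotypeMatrix) -> np.ndarray:
    if gm.n_loci == 0:
        raise ValueError("genotype matrix has zero loci")
    if (gm.dosage == MISSING).any():
        raise ValueError("missing dosages present; run QC filters first")
    return gm.dosage.astype(float)


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 minus the mean identity-by-state allele-sharing proportion."""
    D = _complete_dosage(gm)
    # mean over loci of (2 - |gi - gj|) / 2  ==  1 - cityblock / (2L)
    d = pdist(D, "cityblock") / (2.0 * gm.n_loci)
    return DistanceMatrix.from_condensed(gm.accession_ids, d)


def nei_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Nei standard genetic distance between individuals.

    Each individual is treated as a two-allele population with ALT
    frequency dosage/2.  Identical profiles give 0; pairs with zero
    cross-product (no shared alleles anywhere) give +inf, flagged.
    """
    D = _complete_dosage(gm)
    x = D / 2.0
    L = gm.n_loci
    Jxy = (x @ x.T + (1 - x) @ (1 - x).T) / L
    Jx = np.diag(Jxy)
    with np.errstate(divide="ignore"):
        ratio = Jxy / np.sqrt(np.outer(Jx, Jx))
        values = -np.log(ratio)
    values = np.where(values < 0, 0.0, values)  # clip fp noise at identity
    np.fill_diagonal(values, 0.0)
    dm = DistanceMatrix(gm.accession_ids, values)
    if dm.has_infinite:
        logger.warning("nei_distance: %d pairs share no alleles (distance = +inf)",
                       int(np.isinf(dm.values).sum() // 2))
    return dm


def jaccard_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Jaccard dissimilarity on dosage vectors:
    d = 1 - sum(PQ) / (sum P^2 + sum Q^2 - sum(PQ))."""
    D = _complete_dosage(gm)
    cross = D @ D.T
    sq = np.sum(D**2, axis=1)
    denom = sq[:, None] + sq[None, :] - cross
    zero = denom == 0
    if zero.any():
        warnings.warn("jaccard_distance: all-zero dosage profile pair(s); distance set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 1.0 - cross / np.where(zero, 1.0, denom)
    values[zero] = 0.0
    values = np.clip(values, 0.0, None)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(gm.accession_ids, values)


def rogers_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Modified Rogers distance averaged over loci.

    With individual allele frequencies p = dosage/2, the per-locus term
    sqrt(0.5 [(p_i - p_j)^2 + ((1-p_i) - (1-p_j))^2]) equals |g_i - g_j|/2
    for biallelic loci, so d_R is the mean of those per-locus terms.
    """
    D = _complete_dosage(gm)
    d = pdist(D / 2.0, "cityblock") / gm.n_loci
    return DistanceMatrix.from_condensed(gm.accession_ids, d)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def combine_matrices(
    dm_pheno: DistanceMatrix,
    dm_geno: DistanceMatrix,
    weight: float = 0.5,
) -> DistanceMatrix:
    """Weighted fusion of a phenotypic and a genotypic matrix.

    Each matrix is first rescaled by its own maximum off-diagonal entry so
    both live on [0, 1]; the result is weight * pheno + (1 - weight) * geno.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    dm_geno = dm_geno.reorder(dm_pheno.labels)
    if dm_pheno.has_infinite or dm_geno.has_infinite:
        raise ValueError("cannot combine matrices containing infinite distances")

    def rescaled(dm: DistanceMatrix) -> np.ndarray:
        m = dm.values.max()
        return dm.values / m if m > 0 else dm.values

    values = weight * rescaled(dm_pheno) + (1.0 - weight) * rescaled(dm_geno)
    return DistanceMatrix(dm_pheno.labels, values)


PHENO_MEASURES = {
    "gower": gower,
    "euclidean": euclidean,
    "manhattan": manhattan,
    "mahalanobis": mahalanobis,
}

GENO_MEASURES = {
    "ibs": ibs_distance,
    "jaccard": jaccard_distance,
    "nei": nei_distance,
    "rogers": rogers_distance,
}
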