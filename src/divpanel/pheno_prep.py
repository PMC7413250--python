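"""Adjusted genotype means from trial records and PCA trait selection.

Multi-environment trial observations are reduced to one adjusted mean per
accession and quantitative trait by fitting, trait by trait, the all-fixed-
effects linear model

    value = mu + year + block(year) + genotype [+ genotype x year]

by least squares with sum-to-zero (effects) coding; the adjusted mean is
mu-hat + genotype effect, which averages the estimate over year and block
levels.  For a balanced complete design this reduces to the per-genotype
arithmetic mean.  The genotype-x-year term enters only when the design has
replication within genotype-year cells, more than one year, and every
observed genotype spans at least two years (otherwise the adjusted mean is
not estimable); a rank-deficient design falls back to the minimum-norm
least-squares solution.

Trait selection follows the classic correlation-matrix PCA recipe: traits
are standardized, components with eigenvalue >= ``eigenvalue_min`` are
retained, and a trait is kept when the magnitude of its loading
(eigenvector scaled by sqrt(eigenvalue), i.e. its correlation with the
component) reaches ``loading_min`` on some retained component.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import PhenotypeTable, TrialRecords

logger = logging.getLogger(__name__)

__all__ = ["ls_means", "pca_traits", "select_discriminant_traits", "PCAResult"]


def _effects_code(factor: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: columns for all but the last level;
    rows at the last level get -1 across all columns."""
    k = len(levels)
    if k == 1:
        return np.zeros((len(factor), 0))
    cols = np.zeros((len(factor), k - 1))
    for j, lv in enumerate(levels[:-1]):
        cols[factor == lv, j] = 1.0
    cols[factor == levels[-1], :] = -1.0
    return cols


def _fit_trait(df: pd.DataFrame, genotypes: np.ndarray) -> pd.Series:
    years = np.sort(df["year"].unique())
    y = df["value"].to_numpy(dtype=float)
    X_parts = [np.ones((len(df), 1))]

    year_code = _effects_code(df["year"].to_numpy(), years)
    X_parts.append(year_code)
    # block nested in year: effects coding of block within each year
    for yr in years:
        in_year = (df["year"] == yr).to_numpy()
        blocks = np.sort(df.loc[in_year, "block"].unique())
        code = _effects_code(df["block"].to_numpy(), blocks)
        code[~in_year, :] = 0.0
        X_parts.append(code)

    geno_code = _effects_code(df["accession"].to_numpy(), genotypes)
    X_parts.append(geno_code)

    cells = df.groupby(["accession", "year"]).size()
    replicated = (cells > 1).any()
    years_per_geno = df.groupby("accession")["year"].nunique()
    # GxY is estimable only when every observed genotype spans >= 2 years
    gxy_cols = 0
    if len(years) > 1 and replicated and (years_per_geno >= 2).all():
        gxy = np.einsum("ij,ik->ijk", geno_code, year_code).reshape(len(df), -1)
        X_parts.append(gxy)
        gxy_cols = gxy.shape[1]

    X = np.hstack(X_parts)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    mu = beta[0]
    g_start = X.shape[1] - gxy_cols - geno_code.shape[1]
    g_beta = beta[g_start:g_start + geno_code.shape[1]]
    effects = np.append(g_beta, -g_beta.sum())  # sum-to-zero closes the last level
    means = pd.Series(mu + effects, index=genotypes)

    observed = set(df["accession"])
    unseen = [g for g in genotypes if g not in observed]
    if unseen:
        logger.warning("%d genotypes unobserved for trait %s; means set missing",
                       len(unseen), df["trait"].iloc[0] if "trait" in df else "?")
        means[unseen] = np.nan
    return means


def ls_means(
    records: TrialRecords,
    traits: list[str] | None = None,
    accession_order: list[str] | None = None,
) -> PhenotypeTable:
    """Adjusted (least-squares) genotype means per quantitative trait."""
    df = records.records
    if df.empty:
        raise ValueError("no trial records")
    traits = traits if traits is not None else records.traits
    if accession_order is None:
        accession_order = list(pd.unique(df["accession"]))
    genotypes = np.asarray(accession_order, dtype=object)

    out = {}
    for trait in traits:
        sub = df[df["trait"] == trait]
        if sub.empty:
            raise ValueError(f"trait {trait!r} absent from trial records")
        out[trait] = _fit_trait(sub, genotypes)
    table = pd.DataFrame(out, index=pd.Index(accession_order, name="accession"))
    return PhenotypeTable(table, {t: "quantitative" for t in traits})


@dataclass
class PCAResult:
    """Correlation-matrix PCA of a trait table."""

    eigenvalues: np.ndarray            # nonincreasing
    loadings: pd.DataFrame             # trait x component, correlation scaling
    pct_variance: np.ndarray
    cumulative_pct_variance: np.ndarray
    trait_ids: list[str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca_traits(pheno: PhenotypeTable, traits: list[str] | None = None) -> PCAResult:
    """PCA on the trait correlation matrix.

    Quantitative and ordinal traits enter (ordinal as level ranks); nominal
    traits are excluded.  Constant traits are dropped with a warning.
    Loadings are eigenvectors scaled by sqrt(eigenvalue) and sign-fixed so
    each component's largest-magnitude loading is positive.
    """
    if traits is None:
        traits = pheno.kinds_of(("quantitative", "ordinal"))
    X = pheno.numeric_matrix(traits)
    if np.isnan(X).any():
        # correlation PCA needs complete data; mean-impute with a warning
        warnings.warn("missing trait values mean-imputed for PCA")
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [t for t, k in zip(traits, keep) if not k]
        warnings.warn(f"constant traits excluded from PCA: {dropped}")
        traits = [t for t, k in zip(traits, keep) if k]
        X, sd = X[:, keep], sd[keep]
    if len(traits) < 2:
        raise ValueError("PCA needs at least 2 non-constant quantitative/ordinal traits")

    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    loadings = eigvec * np.sqrt(eigval)[None, :]
    # sign convention: dominant loading of each component is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(len(eigval))])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[None, :]

    pct = 100.0 * eigval / eigval.sum()
    comp_names = [f"PC{i + 1}" for i in range(len(eigval))]
    return PCAResult(
        eigenvalues=eigval,
        loadings=pd.DataFrame(loadings, index=traits, columns=comp_names),
        pct_variance=pct,
        cumulative_pct_variance=np.cumsum(pct),
        trait_ids=list(traits),
    )


def select_discriminant_traits(
    pca: PCAResult,
    eigenvalue_min: float = 1.0,
    loading_min: float = 0.45,
) -> pd.DataFrame:
    """Traits recruited by the retained principal components.

    Components with eigenvalue >= ``eigenvalue_min`` are retained; a trait
    is selected when its max |loading| over those components reaches
    ``loading_min``.  Returns a DataFrame (index = selected traits) with the
    recruiting component and the loading that recruited it.
    """
    retained = np.flatnonzero(pca.eigenvalues >= eigenvalue_min)
    if len(retained) == 0:
        raise ValueError(
            f"no component has eigenvalue >= {eigenvalue_min} "
            f"(max is {pca.eigenvalues.max():.3f}); lower eigenvalue_min"
        )
    sub = pca.loadings.iloc[:, retained]
    best = sub.abs().to_numpy().argmax(axis=1)
    best_load = sub.to_numpy()[np.arange(len(sub)), best]
    selected = np.abs(best_load) >= loading_min
    if not selected.any():
        raise ValueError(f"no trait reaches |loading| >= {loading_min}; lower loading_min")
    out = pd.DataFrame({
        "component": [sub.columns[b] for b in best],
        "loading": best_load,
    }, index=pca.loadings.index)[selected]
    return out
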