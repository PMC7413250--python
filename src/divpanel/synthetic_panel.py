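"""Synthetic germplasm panels with known ground truth.

Emulates a clonally propagated crop diversity panel (the motivating system
is white Guinea yam, *Dioscorea rotundata*): ~173 accessions falling into a
small number of latent genetic groups, genotyped at 10^4-scale biallelic
SNPs and scored for ~30 mixed-type agro-morphological traits in a
multi-year, blocked field trial.

Genotypes follow the Balding–Nichols model: each locus has an ancestral ALT
frequency p drawn uniformly from ``maf_range``; each group's frequency is
Beta(p(1-F)/F, (1-p)(1-F)/F) so that E[p_group] = p and the expected
fixation index among groups is F (= ``fst_target``); dosages are then
Binomial(2, p_group), i.e. Hardy–Weinberg within groups.

Quantitative trait observations decompose as grand mean + group shift +
year + block-within-year + genotype + genotype-x-year + residual, matching
the multi-environment trial model used for adjusted means downstream.
``trait_separation`` scales the between-group shifts in units of the
within-group genotype SD (which is fixed at 1): 0 means groups are
phenotypically indistinguishable, 3 means strongly separated.  Ordinal
traits threshold latent Gaussians into 3–9 levels (field scores are small
integer scales); nominal traits are drawn from group-specific category
probabilities whose divergence also scales with ``trait_separation``.

Every draw flows from ``PanelConfig.seed`` through independent child
streams, so an identical config reproduces the panel bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    TrialRecords,
)

__all__ = ["PanelConfig", "generate_genotypes", "generate_phenotypes", "generate_panel"]


def _default_group_sizes() -> tuple[int, ...]:
    return (58, 58, 57)


@dataclass
class PanelConfig:
    """Simulation truth for one synthetic panel.

    Defaults mirror the study design the package targets: 173 accessions in
    3 groups, 10^4 biallelic SNPs at panel-wide differentiation Fst ~ 0.15,
    ancestral MAF above 0.05, 30 mixed-type traits (20 quantitative,
    7 ordinal, 3 nominal) scored over 2 years x 3 blocks.
    """

    n_accessions: int = 173
    n_groups: int = 3
    group_sizes: tuple[int, ...] = field(default_factory=_default_group_sizes)
    n_snps: int = 10_000
    fst_target: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_quant_traits: int = 20
    n_ordinal_traits: int = 7
    n_nominal_traits: int = 3
    trait_separation: float = 3.0
    n_years: int = 2
    n_blocks: int = 3
    missing_rate: float = 0.0
    seed: int = 0
    # trial-model effect scales (within-group genotype SD is the unit)
    genotype_sd: float = 1.0
    year_sd: float = 0.5
    block_sd: float = 0.3
    ge_sd: float = 0.5
    noise_sd: float = 0.5
    n_chromosomes: int = 20

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_snps < 1 or self.n_accessions < 1:
            raise ValueError("n_accessions, n_groups and n_snps must be positive")
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes length must equal n_groups")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("every group must be non-empty")
        if sum(self.group_sizes) != self.n_accessions:
            raise ValueError(
                f"group_sizes sum {sum(self.group_sizes)} != n_accessions {self.n_accessions}"
            )
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo < hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low < high <= 0.5")
        if self.trait_separation < 0:
            raise ValueError("trait_separation must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_years < 1 or self.n_blocks < 1:
            raise ValueError("n_years and n_blocks must be positive")

    def accession_ids(self) -> list[str]:
        width = len(str(self.n_accessions))
        return [f"ACC{str(i + 1).zfill(width)}" for i in range(self.n_accessions)]

    def group_labels(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_groups), self.group_sizes)


def _rng(config: PanelConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_genotypes(config: PanelConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw a Balding–Nichols genotype panel; returns (matrix, group labels)."""
    rng = _rng(config, 0)
    F = config.fst_target
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_snps)
    if F == 0.0:
        p_group = np.tile(p_anc, (config.n_groups, 1))
    else:
        scale = (1.0 - F) / F
        p_group = rng.beta(p_anc * scale, (1.0 - p_anc) * scale,
                           size=(config.n_groups, config.n_snps))
    groups = config.group_labels()
    dosage = rng.binomial(2, p_group[groups, :]).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING

    # locus map: loci spread over chromosomes, positions strictly increasing
    n_chrom = min(config.n_chromosomes, config.n_snps)
    chrom_of = np.sort(rng.integers(0, n_chrom, size=config.n_snps))
    pos = np.empty(config.n_snps, dtype=int)
    for c in range(n_chrom):
        k = int((chrom_of == c).sum())
        if k:
            pos[chrom_of == c] = np.sort(rng.choice(np.arange(1, 50 * k + 1), size=k, replace=False))
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=config.n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=config.n_snps)) % 4
    meta = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in chrom_of],
        "pos": pos,
        "ref": bases[ref_i],
        "alt": bases[alt_i],
    })
    locus_ids = [f"snp{i + 1}_{meta['chrom'][i]}_{meta['pos'][i]}" for i in range(config.n_snps)]
    gm = GenotypeMatrix(config.accession_ids(), locus_ids, dosage, meta)
    return gm, groups


def _group_trait_means(rng: np.random.Generator, n_traits: int, config: PanelConfig) -> np.ndarray:
    """Per-(trait, group) mean shifts ~ N(0, trait_separation^2), centred per trait."""
    shifts = rng.normal(0.0, 1.0, size=(n_traits, config.n_groups))
    shifts -= shifts.mean(axis=1, keepdims=True)
    return config.trait_separation * shifts


def generate_phenotypes(
    config: PanelConfig, groups: Sequence[int] | np.ndarray
) -> tuple[PhenotypeTable, TrialRecords]:
    """Draw the trait panel for ``groups``; returns (per-accession table, trial records).

    Quantitative and ordinal traits are observed in every year x block cell
    and appear in the trial records; the table carries their per-accession
    summaries (mean for quantitative, median level for ordinal).  Nominal
    traits are stable botanical descriptors, recorded once per accession.
    """
    groups = np.asarray(groups)
    if len(groups) != config.n_accessions:
        raise ValueError("groups length must equal n_accessions")
    rng = _rng(config, 1)
    n = config.n_accessions
    ids = config.accession_ids()
    nq, no, nn = config.n_quant_traits, config.n_ordinal_traits, config.n_nominal_traits
    n_latent = nq + no
    ny, nb = config.n_years, config.n_blocks

    mu = rng.normal(10.0, 3.0, size=n_latent)
    group_shift = _group_trait_means(rng, n_latent, config)  # traits x groups
    genotype_eff = rng.normal(0.0, config.genotype_sd, size=(n, n_latent))
    year_eff = rng.normal(0.0, config.year_sd, size=(ny, n_latent))
    block_eff = rng.normal(0.0, config.block_sd, size=(ny, nb, n_latent))
    ge_eff = rng.normal(0.0, config.ge_sd, size=(n, ny, n_latent))
    noise = rng.normal(0.0, config.noise_sd, size=(n, ny, nb, n_latent))

    # observations: accession x year x block x latent trait
    obs = (
        mu[None, None, None, :]
        + group_shift.T[groups][:, None, None, :]
        + genotype_eff[:, None, None, :]
        + year_eff[None, :, None, :]
        + block_eff[None, :, :, :]
        + ge_eff[:, :, None, :]
        + noise
    )

    quant_names = [f"qt{i + 1}" for i in range(nq)]
    ord_names = [f"ot{i + 1}" for i in range(no)]
    nom_names = [f"nt{i + 1}" for i in range(nn)]

    # ordinal traits: threshold the latent observations into small scales
    n_levels = rng.integers(3, 10, size=no)
    ord_obs = np.empty((n, ny, nb, no), dtype=float)
    for t in range(no):
        latent = obs[:, :, :, nq + t]
        qs = np.quantile(latent, np.linspace(0, 1, n_levels[t] + 1)[1:-1])
        ord_obs[:, :, :, t] = np.searchsorted(qs, latent, side="right").astype(float)

    # nominal traits: group-tilted category probabilities
    nominal_cols = {}
    sep_w = min(1.0, config.trait_separation / 3.0)
    for t in range(nn):
        k = int(rng.integers(3, 6))
        shared = rng.dirichlet(np.full(k, 5.0))
        probs = np.empty((config.n_groups, k))
        for g in range(config.n_groups):
            own = rng.dirichlet(np.full(k, 1.0))
            probs[g] = (1.0 - sep_w) * shared + sep_w * own
            probs[g] /= probs[g].sum()
        draws = np.array([rng.choice(k, p=probs[g]) for g in groups])
        nominal_cols[nom_names[t]] = pd.Categorical.from_codes(
            draws, categories=[f"cat{c + 1}" for c in range(k)]
        )

    # long-format trial records for the replicated (quant + ordinal) traits
    all_rep = np.concatenate([obs[:, :, :, :nq], ord_obs], axis=3)
    rep_names = quant_names + ord_names
    acc_idx, year_idx, block_idx, trait_idx = np.meshgrid(
        np.arange(n), np.arange(ny), np.arange(nb), np.arange(len(rep_names)), indexing="ij"
    )
    records = pd.DataFrame({
        "accession": np.asarray(ids, dtype=object)[acc_idx.ravel()],
        "year": year_idx.ravel() + 1,
        "block": block_idx.ravel() + 1,
        "trait": np.asarray(rep_names, dtype=object)[trait_idx.ravel()],
        "value": all_rep.ravel(),
    })

    table = pd.DataFrame(index=pd.Index(ids, name="accession"))
    for t, name in enumerate(quant_names):
        table[name] = obs[:, :, :, t].mean(axis=(1, 2))
    for t, name in enumerate(ord_names):
        table[name] = np.floor(np.median(ord_obs[:, :, :, t], axis=(1, 2)))
    for name, col in nominal_cols.items():
        table[name] = col

    if config.missing_rate > 0:
        mask = rng.random((n, len(table.columns))) < config.missing_rate
        for j, name in enumerate(table.columns):
            table.loc[mask[:, j], name] = np.nan

    kinds = {**{t: "quantitative" for t in quant_names},
             **{t: "ordinal" for t in ord_names},
             **{t: "nominal" for t in nom_names}}
    levels = {name: list(range(int(n_levels[t]))) for t, name in enumerate(ord_names)}
    pheno = PhenotypeTable(table, kinds, levels)
    return pheno, TrialRecords(records)


def generate_panel(config: PanelConfig):
    """Convenience: genotypes, phenotypes, trial records and truth labels."""
    gm, groups = generate_genotypes(config)
    pheno, records = generate_phenotypes(config, groups)
    truth = pd.DataFrame({"accession": config.accession_ids(), "group": groups + 1})
    return gm, pheno, records, truth
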