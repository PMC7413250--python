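"""Domain containers and file formats for the diversity-panel pipeline.

Four labelled containers travel through every stage:

* :class:`GenotypeMatrix` — accessions x biallelic loci, ALT-dosage coded
  (0/1/2, missing = -1), with per-locus CHROM/POS/REF/ALT metadata.
* :class:`PhenotypeTable` — accessions x traits, each trait declared
  quantitative, ordinal (with an explicit level order) or nominal.
* :class:`TrialRecords` — long-format multi-environment trial observations
  (accession, year, block, trait, value) feeding adjusted-mean computation.
* :class:`DistanceMatrix` — labelled square symmetric dissimilarities; the
  constructor audits symmetry, zero diagonal and nonnegativity so that every
  distance operation inherits those guarantees.

On-disk formats are the field's plain-text standards: VCFv4.2 (GT consumed),
RFC-4180 CSV, PHYLIP square distance matrices and Newick trees.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype dosage
MISSING = -1

TRAIT_KINDS = ("quantitative", "ordinal", "nominal")


class FormatError(ValueError):
    """Raised when an input file or container violates its contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"duplicate {what}: {dupes[:5]}")
    return labels


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a panel of accessions.

    ``dosage[i, l]`` counts ALT alleles of accession ``i`` at locus ``l``
    (0, 1, 2) with :data:`MISSING` for no-calls.  ``locus_meta`` is a
    DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    accession_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    locus_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.accession_ids = _check_unique(self.accession_ids, "accession IDs")
        self.locus_ids = _check_unique(self.locus_ids, "locus IDs")
        d = np.asarray(self.dosage)
        if d.shape != (len(self.accession_ids), len(self.locus_ids)):
            raise FormatError(
                f"dosage shape {d.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(d, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError(f"dosage contains values outside {{0,1,2,{MISSING}}}")
        self.dosage = d.astype(np.int8, copy=False)
        if self.locus_meta is not None and len(self.locus_meta) != len(self.locus_ids):
            raise FormatError("locus_meta length does not match locus_ids")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_loci(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        meta = self.locus_meta.iloc[idx].reset_index(drop=True) if self.locus_meta is not None else None
        return GenotypeMatrix(
            self.accession_ids,
            [self.locus_ids[i] for i in idx],
            self.dosage[:, idx],
            meta,
        )

    def take_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = [pos[a] for a in ids]
        return GenotypeMatrix(list(ids), self.locus_ids, self.dosage[idx], self.locus_meta)

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Return a copy with loci ordered by (chrom, pos)."""
        if self.locus_meta is None:
            return self
        order = np.lexsort(
            (self.locus_meta["pos"].to_numpy(), self.locus_meta["chrom"].astype(str).to_numpy())
        )
        return self.take_loci(order)

    def is_position_sorted(self) -> bool:
        if self.locus_meta is None:
            return True
        chrom = self.locus_meta["chrom"].astype(str).to_numpy()
        pos = self.locus_meta["pos"].to_numpy()
        seen: set[str] = set()
        prev_c: str | None = None
        prev_p = -np.inf
        for c, p in zip(chrom, pos):
            if c != prev_c:
                if c in seen:
                    return False  # chromosome blocks interleaved
                seen.add(c)
                prev_c = c
            elif p < prev_p:
                return False
            prev_p = p
        return True


@dataclass
class PhenotypeTable:
    """Accessions x traits with per-trait measurement kinds.

    Quantitative and ordinal traits are numeric (ordinal values are level
    ranks, 0-based, per the declared ``ordinal_levels`` ordering); nominal
    traits are pandas ``category`` columns.  Missing values are allowed.
    """

    data: pd.DataFrame
    trait_kinds: dict[str, str]
    ordinal_levels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "accession IDs")
        for trait in self.data.columns:
            kind = self.trait_kinds.get(trait)
            if kind not in TRAIT_KINDS:
                raise FormatError(f"trait {trait!r}: unknown kind {kind!r}")
            if kind == "ordinal" and trait not in self.ordinal_levels:
                raise FormatError(f"ordinal trait {trait!r} lacks a declared level order")
            if kind == "nominal" and not isinstance(self.data[trait].dtype, pd.CategoricalDtype):
                self.data[trait] = self.data[trait].astype("category")

    @property
    def accession_ids(self) -> list[str]:
        return [str(x) for x in self.data.index]

    @property
    def trait_ids(self) -> list[str]:
        return list(self.data.columns)

    def kinds_of(self, kinds: Iterable[str]) -> list[str]:
        want = set(kinds)
        return [t for t in self.data.columns if self.trait_kinds[t] in want]

    def select_traits(self, traits: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(
            self.data[list(traits)].copy(),
            {t: self.trait_kinds[t] for t in traits},
            {t: v for t, v in self.ordinal_levels.items() if t in traits},
        )

    def take_accessions(self, ids: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(ids)].copy(), dict(self.trait_kinds), dict(self.ordinal_levels))

    def numeric_matrix(self, traits: Sequence[str] | None = None) -> np.ndarray:
        """Quantitative/ordinal values as a float matrix (NaN for missing)."""
        traits = list(traits) if traits is not None else self.kinds_of(("quantitative", "ordinal"))
        for t in traits:
            if self.trait_kinds[t] == "nominal":
                raise FormatError(f"trait {t!r} is nominal; no numeric representation")
        return self.data[traits].to_numpy(dtype=float)


@dataclass
class TrialRecords:
    """Long-format multi-environment trial observations."""

    records: pd.DataFrame  # columns accession, year, block, trait, value

    REQUIRED = ("accession", "year", "block", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise FormatError(f"trial records missing columns {missing}")
        key = self.records[["accession", "year", "block", "trait"]]
        if key.duplicated().any():
            raise FormatError("duplicate (accession, year, block, trait) keys in trial records")

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.records[self.records["trait"] == trait]

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())


@dataclass
class DistanceMatrix:
    """Labelled square symmetric dissimilarity matrix.

    The constructor enforces the container invariants: square shape matching
    the labels, symmetry within 1e-12, zero diagonal and nonnegative entries.
    ``+inf`` entries are tolerated (Nei distance between profiles sharing no
    alleles) and flagged via :attr:`has_infinite`.
    """

    labels: list[str]
    values: np.ndarray
    has_infinite: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.labels = _check_unique(self.labels, "distance-matrix labels")
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise FormatError(f"distance matrix shape {v.shape} does not match {n} labels")
        if np.isnan(v).any():
            raise FormatError("distance matrix contains NaN")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T):
            raise FormatError("infinite entries are not symmetric")
        both = finite & finite.T
        with np.errstate(invalid="ignore"):
            asym = np.abs(v - v.T)
        if asym[both].max(initial=0.0) > 1e-12:
            raise FormatError("distance matrix is not symmetric within 1e-12")
        if np.abs(np.diag(v)).max(initial=0.0) > 0:
            raise FormatError("distance matrix diagonal is not zero")
        if (v[finite] < 0).any():
            raise FormatError("distance matrix has negative entries")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.has_infinite = bool(np.isinf(v).any())

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strict upper triangle in scipy ``pdist`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    @classmethod
    def from_condensed(cls, labels: Sequence[str], condensed: np.ndarray) -> "DistanceMatrix":
        from scipy.spatial.distance import squareform

        return cls(list(labels), squareform(condensed, checks=False))

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            extra = sorted(set(labels) - set(self.labels))
            missing = sorted(set(self.labels) - set(labels))
            raise FormatError(f"label mismatch: extra={extra[:5]}, missing={missing[:5]}")
        pos = {a: i for i, a in enumerate(self.labels)}
        idx = np.array([pos[a] for a in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """Agglomeration history: a scipy linkage matrix plus leaf labels.

    ``merge_matrix`` rows are ``(left, right, height, size)`` in scipy
    convention: indices below ``n`` are leaves, index ``n + i`` is the
    cluster formed by merge ``i``.
    """

    labels: list[str]
    merge_matrix: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = _check_unique(self.labels, "dendrogram labels")
        Z = np.asarray(self.merge_matrix, dtype=float)
        n = len(self.labels)
        if Z.shape != (n - 1, 4):
            raise FormatError(f"expected {n - 1} merges for {n} leaves, got shape {Z.shape}")
        self.merge_matrix = Z

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merge_matrix[:, 2]


def harmonize_accessions(
    gm: GenotypeMatrix, pheno: PhenotypeTable, join: str = "strict"
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Align genotype and phenotype accession sets.

    ``join='strict'`` (reader default) rejects any mismatch; ``join='inner'``
    intersects with a logged report, preserving genotype order.
    """
    g, p = set(gm.accession_ids), set(pheno.accession_ids)
    if join == "strict":
        if g != p:
            raise FormatError(
                f"accession sets differ (genotype-only: {sorted(g - p)[:5]}, "
                f"phenotype-only: {sorted(p - g)[:5]}); pass join='inner' to intersect"
            )
        common = gm.accession_ids
    elif join == "inner":
        keep = g & p
        if not keep:
            raise FormatError("no accessions shared between genotype and phenotype inputs")
        common = [a for a in gm.accession_ids if a in keep]
        logger.info(
            "inner join of accession sets: kept %d, dropped %d genotype-only and %d phenotype-only",
            len(common), len(g - keep), len(p - keep),
        )
    else:
        raise ValueError(f"unknown join {join!r}")
    return gm.take_accessions(common), pheno.take_accessions(common)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    gq_min: float | None = None,
    dp_min: float | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into ALT-dosage coding.

    Multi-allelic and non-SNP records are dropped (with a logged count);
    half-missing calls ("./1") become missing.  When ``gq_min``/``dp_min``
    are given and the VCF carries GQ/DP FORMAT fields, calls failing the
    thresholds are set to missing; absent fields are skipped with a log line.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # malformed header and friends
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = _check_unique(vcf.samples, "VCF sample IDs")

    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    meta_rows: list[tuple] = []
    dropped = {"multiallelic": 0, "non_snp": 0}
    warned_fields: set[str] = set()
    bases = {"A", "C", "G", "T"}
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if var.REF.upper() not in bases or var.ALT[0].upper() not in bases:
            dropped["non_snp"] += 1
            continue
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        dos = np.empty(len(samples), dtype=np.int8)
        for s, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            dos[s] = MISSING if (a < 0 or b < 0) else a + b
        for name, cutoff in (("GQ", gq_min), ("DP", dp_min)):
            if cutoff is None:
                continue
            try:
                vals = var.format(name)
            except KeyError:
                vals = None
            if vals is None:
                if name not in warned_fields:
                    logger.info("FORMAT field %s absent; %s filter skipped", name, name)
                    warned_fields.add(name)
                continue
            vals = np.asarray(vals, dtype=float).reshape(len(samples), -1)[:, 0]
            dos[~(vals > cutoff)] = MISSING
        rows.append(dos)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        locus_ids.append(vid)
        meta_rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if dropped["multiallelic"] or dropped["non_snp"]:
        logger.info(
            "read_vcf dropped %d multi-allelic and %d non-SNP records",
            dropped["multiallelic"], dropped["non_snp"],
        )
    if not rows:
        raise FormatError(f"no biallelic SNP records in {path}")
    dosage = np.stack(rows, axis=1)
    meta = pd.DataFrame(meta_rows, columns=["chrom", "pos", "ref", "alt"])
    gm = GenotypeMatrix(samples, locus_ids, dosage, meta)
    gm.drop_counts = dropped  # type: ignore[attr-defined]
    return gm


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT-only FORMAT."""
    meta = gm.locus_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if meta is not None:
            for chrom in pd.unique(meta["chrom"].astype(str)):
                fh.write(f"##contig=<ID={chrom}>\n")
        else:
            fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.accession_ids) + "\n")
        for l in range(gm.n_loci):
            if meta is not None:
                chrom, pos, ref, alt = meta.iloc[l][["chrom", "pos", "ref", "alt"]]
            else:
                chrom, pos, ref, alt = "1", l + 1, "A", "G"
            gts = "\t".join(_GT_STRING[int(d)] for d in gm.dosage[:, l])
            fh.write(f"{chrom}\t{pos}\t{gm.locus_ids[l]}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# phenotype / trial CSV
# ---------------------------------------------------------------------------

def read_phenotypes(
    path: str | Path,
    trait_kinds: Mapping[str, str],
    ordinal_levels: Mapping[str, list] | None = None,
    id_column: str = "accession",
) -> PhenotypeTable:
    """Read an accession x trait CSV, coercing each column per declared kind."""
    df = pd.read_csv(path, dtype={id_column: str})
    if id_column not in df.columns:
        raise FormatError(f"phenotype CSV lacks ID column {id_column!r}")
    if df[id_column].duplicated().any():
        raise FormatError("duplicate accession IDs in phenotype CSV")
    df = df.set_index(id_column)
    ordinal_levels = dict(ordinal_levels or {})
    out = {}
    for trait in df.columns:
        kind = trait_kinds.get(trait)
        if kind is None:
            raise FormatError(f"trait {trait!r} has no declared kind")
        if kind == "quantitative":
            out[trait] = pd.to_numeric(df[trait], errors="raise")
        elif kind == "ordinal":
            if trait not in ordinal_levels:
                raise FormatError(f"ordinal trait {trait!r} lacks a declared level order")
            levels = ordinal_levels[trait]
            rank = {lv: r for r, lv in enumerate(levels)}
            col = df[trait]
            unknown = set(col.dropna()) - set(rank) - {""}
            # numeric level lists read back as strings: retry numerically
            if unknown:
                try:
                    col = pd.to_numeric(col)
                    rank = {float(lv): r for r, lv in enumerate(levels)}
                    unknown = set(col.dropna()) - set(rank)
                except (ValueError, TypeError):
                    pass
            if unknown:
                raise FormatError(f"ordinal trait {trait!r}: undeclared levels {sorted(map(str, unknown))[:5]}")
            out[trait] = col.map(rank).astype(float)
        elif kind == "nominal":
            out[trait] = df[trait].astype("category")
        else:
            raise FormatError(f"trait {trait!r}: unknown kind {kind!r}")
    table = pd.DataFrame(out, index=df.index)
    table.index = table.index.astype(str)
    return PhenotypeTable(table, dict(trait_kinds), {t: list(v) for t, v in ordinal_levels.items()})


def write_phenotypes(pheno: PhenotypeTable, path: str | Path, id_column: str = "accession") -> None:
    df = pheno.data.copy()
    df.index.name = id_column
    df.to_csv(path)


def read_trial_records(path: str | Path) -> TrialRecords:
    df = pd.read_csv(path, dtype={"accession": str, "trait": str})
    return TrialRecords(df)


def write_trial_records(records: TrialRecords, path: str | Path) -> None:
    records.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# distance matrices, memberships, trees
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path: str | Path, dialect: str = "csv") -> None:
    """Write a square distance matrix as labelled CSV or PHYLIP square."""
    if dialect == "csv":
        dm.to_dataframe().to_csv(path, quoting=csv.QUOTE_MINIMAL, float_format="%.12g")
    elif dialect == "phylip":
        for lab in dm.labels:
            if any(ch.isspace() for ch in lab):
                raise FormatError(f"PHYLIP labels may not contain whitespace: {lab!r}")
        with open(path, "w") as fh:
            fh.write(f"{dm.n}\n")
            for lab, row in zip(dm.labels, dm.values):
                fh.write(lab + "  " + "  ".join(f"{x:.10f}" for x in row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix([str(x) for x in df.index], df.to_numpy(dtype=float))


def write_memberships(assignment, path: str | Path) -> None:
    pd.DataFrame(
        {"accession": assignment.labels, "cluster": assignment.clusters}
    ).to_csv(path, index=False)


def _escape_newick(label: str) -> str:
    if any(c in label for c in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def dendrogram_to_newick(dendro: Dendrogram) -> str:
    """Render an agglomeration as an ultrametric Newick string.

    Branch lengths place each merge at half its height, so two leaves joined
    at height *h* each get a terminal branch of *h*/2 (cophenetic distance is
    twice the path midpoint, the ultrametric convention).
    """
    n = dendro.n_leaves
    Z = dendro.merge_matrix

    def node_height(i: int) -> float:
        return 0.0 if i < n else Z[i - n, 2]

    def render(i: int) -> str:
        if i < n:
            return _escape_newick(dendro.labels[i])
        left, right, h = int(Z[i - n, 0]), int(Z[i - n, 1]), Z[i - n, 2]
        parts = []
        for child in (left, right):
            bl = (h - node_height(child)) / 2.0
            parts.append(f"{render(child)}:{bl:.10g}")
        return "(" + ",".join(parts) + ")"

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        return render(2 * n - 2) + ";"
    finally:
        sys.setrecursionlimit(old)


def write_newick(dendro: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram_to_newick(dendro) + "\n")
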