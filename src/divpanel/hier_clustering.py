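"""Agglomerative clustering, cophenetic analysis and partition comparison.

The six Lance–Williams linkages used for panel dendrograms are computed by
``scipy.cluster.hierarchy`` from a precomputed dissimilarity matrix:

====================  ==================  =========================================
panel name            scipy method        update rule
====================  ==================  =========================================
single                single              minimum
complete              complete            maximum
average (UPGMA)       average             size-weighted mean
mcquitty (WPGMA)      weighted            simple mean of the two merged clusters
median (WPGMC)        median              LW on squared distances, a=1/2, b=-1/4
ward.D2               ward                LW on squared distances, sqrt heights
====================  ==================  =========================================

Median linkage can invert heights; they are reported as computed, and
cophenetic distances use the raw merge heights.  Model selection follows
the cophenetic-correlation recipe: build every (dissimilarity, linkage)
dendrogram, correlate its cophenetic distances with the input, and retain
the argmax cell.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .formats_io import Dendrogram, DistanceMatrix

__all__ = [
    "LINKAGE_METHODS", "linkage", "cophenetic_distances", "cophenetic_correlation",
    "ccc_grid", "cut_tree", "membership_concordance",
    "ClusterAssignment", "CCCGrid",
]

#: panel-convention linkage names -> scipy method names
LINKAGE_METHODS = {
    "ward.D2": "ward",
    "single": "single",
    "average": "average",
    "median": "median",
    "mcquitty": "weighted",
    "complete": "complete",
}


def linkage(dm: DistanceMatrix, method: str) -> Dendrogram:
    """Agglomerate a distance matrix under one of the six linkage rules."""
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage {method!r}; choose from {sorted(LINKAGE_METHODS)}")
    if dm.n < 2:
        raise ValueError("need at least 2 items to cluster")
    if dm.has_infinite:
        raise ValueError("cannot cluster a matrix with infinite distances")
    Z = sch.linkage(dm.condensed(), method=LINKAGE_METHODS[method])
    return Dendrogram(dm.labels, Z, method=method)


def cophenetic_distances(dendro: Dendrogram) -> DistanceMatrix:
    """Pairwise heights of the lowest merge joining each leaf pair."""
    return DistanceMatrix.from_condensed(dendro.labels, sch.cophenet(dendro.merge_matrix))


def cophenetic_correlation(dm: DistanceMatrix, dendro: Dendrogram) -> float:
    """Pearson correlation between input and cophenetic upper triangles."""
    coph = cophenetic_distances(dendro).reorder(dm.labels)
    x, y = dm.condensed(), coph.condensed()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("cophenetic correlation undefined: zero variance in distances")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CCCGrid:
    """Cophenetic correlations for every (dissimilarity, linkage) pair."""

    table: pd.DataFrame                      # measures x methods, NaN = failed cell
    errors: dict[tuple[str, str], str]
    dendrograms: dict[tuple[str, str], Dendrogram]

    def best_for(self, measure: str) -> tuple[str, float]:
        row = self.table.loc[measure]
        method = row.idxmax()
        if pd.isna(row[method]):
            raise ValueError(f"every linkage failed for measure {measure!r}")
        return str(method), float(row[method])

    def argmax(self) -> tuple[str, str, float]:
        """(measure, method, ccc) of the globally best cell."""
        t = self.table
        if t.isna().all().all():
            raise ValueError("every grid cell failed")
        idx = np.unravel_index(np.nanargmax(t.to_numpy()), t.shape)
        return str(t.index[idx[0]]), str(t.columns[idx[1]]), float(t.iloc[idx])


def ccc_grid(
    dms: dict[str, DistanceMatrix],
    methods: list[str] | None = None,
) -> CCCGrid:
    """Full cophenetic-correlation grid over named matrices and linkages.

    Per-cell failures (e.g. zero-variance distances) become NaN cells with
    recorded reasons rather than aborting the grid.
    """
    if not dms:
        raise ValueError("no distance matrices given")
    methods = list(methods) if methods is not None else list(LINKAGE_METHODS)
    table = pd.DataFrame(np.nan, index=list(dms), columns=methods, dtype=float)
    errors: dict[tuple[str, str], str] = {}
    dendros: dict[tuple[str, str], Dendrogram] = {}
    for name, dm in dms.items():
        for method in methods:
            try:
                dendro = linkage(dm, method)
                table.loc[name, method] = cophenetic_correlation(dm, dendro)
                dendros[(name, method)] = dendro
            except ValueError as exc:
                errors[(name, method)] = str(exc)
    return CCCGrid(table, errors, dendros)


@dataclass
class ClusterAssignment:
    """A flat partition: cluster index (1..k) per accession."""

    labels: list[str]
    clusters: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.clusters = np.asarray(self.clusters, dtype=int)
        if len(self.clusters) != len(self.labels):
            raise ValueError("cluster vector length does not match labels")
        present = set(self.clusters.tolist())
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"cluster indices {sorted(present)} are not exactly 1..{self.k}")

    def sizes(self) -> dict[int, int]:
        return {c: int((self.clusters == c).sum()) for c in range(1, self.k + 1)}


def cut_tree(dendro: Dendrogram, k: int) -> ClusterAssignment:
    """Cut to exactly k clusters by undoing the k-1 last merges.

    Ties in merge height are resolved by merge order (later merges undone
    first), which is scipy's ``cut_tree`` semantics.  Cluster indices are
    renumbered 1..k by first appearance in leaf order.
    """
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}")
    raw = sch.cut_tree(dendro.merge_matrix, n_clusters=k).ravel()
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        out[i] = remap[c]
    return ClusterAssignment(dendro.labels, out, k)


def _align_to(reference: ClusterAssignment, other: ClusterAssignment) -> np.ndarray:
    """Relabel ``other``'s clusters to maximize overlap with ``reference``
    (optimal assignment on the contingency table)."""
    table = np.zeros((reference.k, other.k))
    for rc, oc in zip(reference.clusters, other.clusters):
        table[rc - 1, oc - 1] += 1
    rows, cols = linear_sum_assignment(-table)
    mapping = {int(c) + 1: int(r) + 1 for r, c in zip(rows, cols)}
    nxt = reference.k + 1
    out = np.empty_like(other.clusters)
    for i, c in enumerate(other.clusters):
        if c not in mapping:
            mapping[c] = nxt
            nxt += 1
        out[i] = mapping[c]
    return out


def membership_concordance(assignments: dict[str, ClusterAssignment]) -> dict:
    """Concordance of 2 or 3 partitions over one accession set.

    Clusters are aligned across assignments by maximum-overlap matching
    against the first partition; returns per-pair concordant counts and
    adjusted Rand indices plus the count of accessions concordant in all
    partitions (the Venn-diagram core).
    """
    names = list(assignments)
    if len(names) not in (2, 3):
        raise ValueError("membership_concordance expects 2 or 3 assignments")
    ref = assignments[names[0]]
    for name in names[1:]:
        if assignments[name].labels != ref.labels:
            raise ValueError(f"label sets/order differ between {names[0]!r} and {name!r}")

    aligned = {names[0]: ref.clusters}
    for name in names[1:]:
        aligned[name] = _align_to(ref, assignments[name])

    result: dict = {"n": len(ref.labels), "pairwise": {}, "ari": {}}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            result["pairwise"][f"{a}|{b}"] = int((aligned[a] == aligned[b]).sum())
            result["ari"][f"{a}|{b}"] = float(
                adjusted_rand_score(assignments[a].clusters, assignments[b].clusters)
            )
    stacked = np.vstack([aligned[n] for n in names])
    result["all_concordant"] = int((stacked == stacked[0]).all(axis=0).sum())
    return result
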