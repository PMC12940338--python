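"""Binary-trait distances and WPGMA hierarchical clustering.

Individuals are scored for presence (1) / absence (0) of discrete
traits, possibly with missing entries.  Dummy traits — always present
or always absent across all scored cases — carry no information and are
excluded.  The pairwise distance is the simple mismatch proportion: the
number of traits present in one individual and absent in the other
(patterns 10 or 01) divided by the number of traits observed in both
(including joint presences 11 and joint absences 00).  Trees are built
with WPGMA (weighted pair-group method with arithmetic mean): the
distance from a merged cluster to any other is the plain average of its
two constituents' distances, regardless of cluster size.  Clustering on
squared distances ("squared Euclidean interval") is the default and can
be switched off.

The WPGMA merge loop is implemented here directly so that tie-breaking
is fully specified (lowest-index cluster pair first); the merge table
uses the SciPy linkage layout, so SciPy's dendrogram/cut utilities apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "drop_dummy_traits",
    "mismatch_distance",
    "wpgma",
    "cophenetic",
    "cut_clusters",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with the trait counts used."""

    labels: list[str]
    values: np.ndarray
    denominators: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("self-distances must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """WPGMA merge tree in SciPy linkage layout.

    ``merges`` has one row per merge: [cluster_a, cluster_b, height,
    size]; leaves are numbered 0..n-1 in label order, internal clusters
    n, n+1, ...  ``squared`` records whether heights are on the squared
    distance scale.
    """

    merges: np.ndarray
    labels: list[str]
    squared: bool = True


def drop_dummy_traits(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove dummy traits: columns constant across all scored cases.

    A column whose observed (non-missing) entries are all equal carries
    no distance information and is dropped; the removal log names the
    dropped columns.  Raises if nothing informative remains.
    """
    dropped = []
    for col in matrix.columns:
        observed = matrix[col].dropna()
        if observed.nunique() <= 1:
            dropped.append(col)
    kept = matrix.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all traits are dummy (constant); nothing to analyze")
    return kept, dropped


def mismatch_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise mismatch proportion over jointly observed traits.

    d(i, j) = (#10 + #01) / (#10 + #01 + #11 + #00), the denominators
    counting only traits scored in both individuals (pairwise-complete).
    The per-pair denominators are returned alongside the distances.
    """
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("duplicate individual or trait labels")
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals for distances")
    obs = ~np.isnan(values)
    d = np.zeros((n, n))
    denom = np.zeros((n, n), dtype=int)
    for i in range(n):
        denom[i, i] = int(obs[i].sum())
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"individuals {matrix.index[i]!r} and {matrix.index[j]!r} "
                    "share no observed traits"
                )
            mism = float(np.sum(values[i, both] != values[j, both]))
            d[i, j] = d[j, i] = mism / m
            denom[i, j] = denom[j, i] = m
    return DistanceMatrix(
        labels=[str(x) for x in matrix.index], values=d, denominators=denom
    )


def wpgma(dist: DistanceMatrix, square_first: bool = True) -> Dendrogram:
    """WPGMA agglomeration with deterministic lowest-index tie-breaking.

    With ``square_first`` (default) clustering operates on squared
    distances.  At each step the closest active pair merges at their
    current distance; the merged cluster's distance to any third cluster
    is the unweighted mean of its two members' distances.
    """
    d = dist.values.astype(float).copy()
    if square_first:
        d = d**2
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    # active clusters: position -> (cluster id, member count for bookkeeping)
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        m = len(ids)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                # strict < keeps the first (lowest-index) pair on ties
                if best is None or d[a, b] < best[0]:
                    best = (d[a, b], a, b)
        height, a, b = best
        ia, ib = ids[a], ids[b]
        size = sizes[ia] + sizes[ib]
        merges[step] = [min(ia, ib), max(ia, ib), height, size]
        # WPGMA update: average of the two constituent distances
        new_row = 0.5 * (d[a, :] + d[b, :])
        d[a, :] = new_row
        d[:, a] = new_row
        d[a, a] = 0.0
        d = np.delete(np.delete(d, b, axis=0), b, axis=1)
        ids[a] = next_id
        sizes[next_id] = size
        del ids[b]
        next_id += 1
    return Dendrogram(merges=merges, labels=list(dist.labels), squared=square_first)


def cophenetic(dend: Dendrogram) -> DistanceMatrix:
    """Cophenetic distances: merge height of the smallest shared cluster."""
    n = len(dend.labels)
    if n == 1:
        return DistanceMatrix(labels=list(dend.labels), values=np.zeros((1, 1)))
    condensed = hierarchy.cophenet(dend.merges)
    return DistanceMatrix(labels=list(dend.labels), values=squareform(condensed))


def cut_clusters(dend: Dendrogram, k: int) -> np.ndarray:
    """Flat cluster labels (1..k) from cutting the tree into k groups."""
    return hierarchy.fcluster(dend.merges, t=k, criterion="maxclust")


def to_newick(dend: Dendrogram) -> str:
    """Newick string with ultrametric branch lengths from merge heights."""
    n = len(dend.labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: dend.labels[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(dend.merges):
        a, b = int(a), int(b)
        new = n + step
        # each node sits at half its merge height, so the tree is ultrametric
        la = (h - height[a]) / 2.0
        lb = (h - height[b]) / 2.0
        node[new] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[new] = h
    return node[n + len(dend.merges) - 1] + ";"
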