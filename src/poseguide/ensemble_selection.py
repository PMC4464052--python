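"""Representative protein-structure selection from pocket similarity.

Binding-pocket similarity between protein variants is consumed as a
precomputed symmetric matrix with unit diagonal (computing it is an
external concern).  Three selection strategies are provided:

* ``choose_exemplars`` — K-medoid partitioning on distance 1 - similarity,
  with each cluster represented by the member of maximal mean similarity
  to its co-members.  This mirrors centroid-style clustering when only
  pairwise similarities exist and exemplars must be actual structures.
* ``choose_diverse`` — greedy max-min-distance selection seeded with the
  globally most dissimilar structure.  By construction this picks
  outliers, which is exactly why it tends to underperform as an
  ensemble-selection strategy.
* ``choose_random`` — seeded uniform sampling without replacement, the
  baseline strategy.

A single-linkage agglomeration over the same matrix yields the mutual
similarity tree (exportable as Newick with merge similarities annotated).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

#: switch to stochastic PAM above this many candidate medoid sets
_EXACT_SEARCH_LIMIT = 5000
DEFAULT_RESTARTS = 100


@dataclass
class PocketSimMatrix:
    """Symmetric N x N pocket-similarity matrix with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match the number of ids")
        if n < 1:
            raise ValueError("empty matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix must be symmetric within 1e-9")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("diagonal must be 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def distances(self) -> np.ndarray:
        """Distance transform d = 1 - similarity, zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    @classmethod
    def read(cls, path) -> "PocketSimMatrix":
        """Square TSV/CSV with header ids and matching index column."""
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(ids=[str(c) for c in df.columns], values=df.to_numpy(float))

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep=sep
        )


@dataclass
class EnsembleSelection:
    """K chosen exemplar structures with the induced cluster assignment."""

    exemplar_ids: list[str]
    assignment: list[int]
    strategy: str
    objective: float


@dataclass
class SimilarityTree:
    """Single-linkage merge tree; merge values are similarities at merge."""

    ids: list[str]
    merges: list[tuple[int, int, float]]  # (node_a, node_b, similarity)

    def to_newick(self) -> str:
        n = len(self.ids)
        labels = {i: name for i, name in enumerate(self.ids)}
        for k, (a, b, sim) in enumerate(self.merges):
            labels[n + k] = f"({labels[a]},{labels[b]}){sim:.6g}"
        root = n + len(self.merges) - 1 if self.merges else 0
        return labels[root] + ";"


def _validate_k(matrix: PocketSimMatrix, k: int) -> None:
    if not 1 <= k <= matrix.n:
        raise ValueError(f"k={k} out of range 1..{matrix.n}")


def _assign(dist: np.ndarray, medoids: tuple[int, ...]) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment (index into medoid tuple) and objective
    (mean over items of distance to their medoid).  Ties go to the
    earlier medoid in the tuple."""
    sub = dist[:, list(medoids)]
    labels = sub.argmin(axis=1)
    obj = float(sub[np.arange(len(dist)), labels].mean())
    return labels, obj


def _exemplar_of(sim: np.ndarray, cluster: list[int]) -> int:
    """Member with maximal mean similarity to co-members (ties: lowest index)."""
    if len(cluster) == 1:
        return cluster[0]
    sub = sim[np.ix_(cluster, cluster)]
    means = (sub.sum(axis=1) - 1.0) / (len(cluster) - 1)
    return cluster[int(means.argmax())]


def choose_exemplars(
    matrix: PocketSimMatrix,
    k: int,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> EnsembleSelection:
    """K-medoid partition of the structures on d = 1 - similarity.

    When the number of candidate medoid sets C(N, k) is small the optimum
    is found by exhaustive search; otherwise seeded multi-restart PAM-style
    alternation (assign to nearest medoid, re-pick each cluster's medoid)
    is used.  Final exemplars are re-expressed as the member of each
    cluster with maximal mean similarity to co-members.  Deterministic
    given the seed; ties broken by identifier order.
    """
    _validate_k(matrix, k)
    dist = matrix.distances()
    n = matrix.n

    if math.comb(n, k) <= _EXACT_SEARCH_LIMIT:
        best: tuple[float, tuple[int, ...]] | None = None
        for medoids in itertools.combinations(range(n), k):
            _, obj = _assign(dist, medoids)
            cand = (obj, medoids)
            if best is None or cand < best:
                best = cand
        medoids = best[1]
    else:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(restarts):
            medoids = tuple(sorted(rng.choice(n, size=k, replace=False)))
            for _ in range(100):
                labels, _ = _assign(dist, medoids)
                new = []
                for j in range(k):
                    cluster = [i for i in range(n) if labels[i] == j]
                    if not cluster:
                        new.append(medoids[j])
                        continue
                    sub = dist[np.ix_(cluster, cluster)]
                    new.append(cluster[int(sub.mean(axis=1).argmin())])
                new = tuple(sorted(set(new)))
                if len(new) < k:  # collapsed clusters: keep previous medoids
                    new = medoids
                if new == medoids:
                    break
                medoids = new
            _, obj = _assign(dist, medoids)
            cand = (obj, medoids)
            if best is None or cand < best:
                best = cand
        medoids = best[1]

    labels, obj = _assign(dist, medoids)
    exemplars = []
    final_labels = [int(x) for x in labels]
    for j in range(k):
        cluster = [i for i in range(n) if labels[i] == j]
        exemplars.append(_exemplar_of(matrix.values, cluster) if cluster else medoids[j])
    return EnsembleSelection(
        exemplar_ids=[matrix.ids[e] for e in exemplars],
        assignment=final_labels,
        strategy="kmedoid",
        objective=obj,
    )


def choose_diverse(matrix: PocketSimMatrix, k: int) -> EnsembleSelection:
    """Greedy maximally-dissimilar selection.

    Seeded with the structure of lowest mean similarity to all others;
    each subsequent pick maximises the minimum distance to the already
    selected set.  Ties broken by identifier sort order.
    """
    _validate_k(matrix, k)
    n = matrix.n
    dist = matrix.distances()
    order = sorted(range(n), key=lambda i: matrix.ids[i])
    mean_sim = (matrix.values.sum(axis=1) - 1.0) / max(n - 1, 1)
    start = min(order, key=lambda i: (mean_sim[i], matrix.ids[i]))
    chosen = [start]
    while len(chosen) < k:
        pick, pick_d = None, -1.0
        for i in order:  # id-sorted: lexicographically first id wins ties
            if i in chosen:
                continue
            d = float(dist[i, chosen].min())
            if d > pick_d:
                pick, pick_d = i, d
        chosen.append(pick)
    sub = dist[:, chosen]
    labels = sub.argmin(axis=1)
    obj = float(sub[np.arange(n), labels].mean())
    return EnsembleSelection(
        exemplar_ids=[matrix.ids[i] for i in chosen],
        assignment=[int(x) for x in labels],
        strategy="diverse",
        objective=obj,
    )


def choose_random(matrix: PocketSimMatrix, k: int, seed: int = 0) -> EnsembleSelection:
    """Uniform sample of k structures without replacement (seeded)."""
    _validate_k(matrix, k)
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(matrix.n, size=k, replace=False).tolist())
    dist = matrix.distances()
    sub = dist[:, chosen]
    labels = sub.argmin(axis=1)
    obj = float(sub[np.arange(matrix.n), labels].mean())
    return EnsembleSelection(
        exemplar_ids=[matrix.ids[i] for i in chosen],
        assignment=[int(x) for x in labels],
        strategy="random",
        objective=obj,
    )


def single_linkage_tree(matrix: PocketSimMatrix) -> SimilarityTree:
    """Single-linkage agglomeration on d = 1 - similarity.

    Merge annotations store the similarity (1 - merge distance); merge
    similarities are non-increasing from leaves to root.
    """
    n = matrix.n
    if n == 1:
        return SimilarityTree(ids=list(matrix.ids), merges=[])
    condensed = squareform(matrix.distances(), checks=False)
    z = linkage(condensed, method="single")
    merges = [(int(a), int(b), 1.0 - float(d)) for a, b, d, _ in z]
    return SimilarityTree(ids=list(matrix.ids), merges=merges)
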