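"""Directed KNN sample-correlation graph over autoencoder embeddings.

Each sample node keeps the k samples nearest to it in Euclidean embedding
distance, nearest first, ties broken by ascending sample index.  The graph is
directed and not symmetrized: the zero-filling rule averages over "the
neighbors of sample i", which is a per-target neighborhood of fixed size k.
KNN is exact (all-pairs distances); microbiome cohorts are small enough that
an approximate index would buy nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SampleGraph", "build_knn_graph"]

DEFAULT_K = 5


@dataclass(frozen=True)
class SampleGraph:
    """Directed KNN graph: adjacency A (n x n, {0,1}, zero diagonal) and
    per-node ordered neighborhoods (nearest first)."""

    n: int
    k: int
    adjacency: np.ndarray          # (n, n) uint8
    neighborhoods: np.ndarray      # (n, k) int, row a = N_a ordered by distance
    distances: np.ndarray          # (n, k) matching neighborhoods

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.shape != (self.n, self.n) or np.any(np.diag(A) != 0):
            raise ValueError("adjacency must be n x n with a zero diagonal")
        if self.neighborhoods.shape != (self.n, self.k):
            raise ValueError("neighborhoods must be n x k")

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def write_edge_list(self, path: str | Path) -> None:
        """Export as TSV: source, target, rank (0 = nearest), distance."""
        with open(path, "w") as fh:
            fh.write("source\ttarget\trank\tdistance\n")
            for a in range(self.n):
                for rank in range(self.k):
                    fh.write(
                        f"{a}\t{self.neighborhoods[a, rank]}\t{rank}\t"
                        f"{self.distances[a, rank]:.10g}\n"
                    )


def build_knn_graph(Z: np.ndarray, k: int = DEFAULT_K) -> SampleGraph:
    """Exact k-nearest-neighbor graph on embeddings Z (n x d), Euclidean.

    Matches a brute-force all-pairs computation exactly; ties in distance are
    broken by ascending sample index (a stable argsort over the distance row).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("embeddings must be 2-D (samples x dims)")
    if not np.all(np.isfinite(Z)):
        raise ValueError("embeddings contain non-finite entries")
    n = Z.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must satisfy 1 <= k <= n-1, got k={k}, n={n}")

    dist = cdist(Z, Z, metric="euclidean")
    np.fill_diagonal(dist, np.inf)
    # stable sort: equal distances keep ascending index order
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    ndist = np.take_along_axis(dist, order, axis=1)

    A = np.zeros((n, n), dtype=np.uint8)
    A[np.repeat(np.arange(n), k), order.ravel()] = 1
    return SampleGraph(n=n, k=k, adjacency=A, neighborhoods=order, distances=ndist)
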