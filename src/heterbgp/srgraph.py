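"""DTW distances between unequal-length records and the sparse relation graph.

Every record is a node; each node gets a directed edge to its K nearest
neighbours under dynamic time warping distance. The adjacency is augmented
with self-loops and symmetrically degree-normalized into the propagation
matrix consumed by the graph layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "SRGraph",
    "dtw_distance",
    "distance_matrix",
    "topk_adjacency",
    "build_srgraph",
]


def _dtw_dp(a: np.ndarray, b: np.ndarray) -> float:
    # Classic O(L1*L2) dynamic program, two-row rolling buffer.
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m)
    curr = np.empty(m)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        curr[0] = prev[0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = best + abs(a[i] - b[j])
        prev, curr = curr, prev
    return float(prev[m - 1])


def _dtw_dp_banded(a: np.ndarray, b: np.ndarray, band: int) -> float:
    n, m = a.shape[0], b.shape[0]
    inf = np.inf
    prev = np.full(m, inf)
    curr = np.full(m, inf)
    width = band + abs(n - m)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, min(m, width + 1)):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        lo = max(0, i - width)
        hi = min(m - 1, i + width)
        curr[:] = inf
        for j in range(lo, hi + 1):
            best = prev[j]
            if j > 0:
                if prev[j - 1] < best:
                    best = prev[j - 1]
                if curr[j - 1] < best:
                    best = curr[j - 1]
            curr[j] = best + abs(a[i] - b[j])
        prev, curr = curr, prev
    return float(prev[m - 1])


try:  # numba gives ~100x on long records; plain numpy DP is the fallback
    from numba import njit

    _dtw_dp = njit(cache=True, fastmath=False)(_dtw_dp)
    _dtw_dp_banded = njit(cache=True, fastmath=False)(_dtw_dp_banded)
except ImportError:  # pragma: no cover - exercised only without numba
    pass


def dtw_distance(a, b, band: int | None = None) -> float:
    """Dynamic time warping distance with absolute-difference local cost.

    Step moves are (1,0), (0,1), (1,1); the alignment path is anchored at
    both series' endpoints. ``band`` optionally restricts the warping path
    to a Sakoe-Chiba band of that half-width (speed knob; exact when None).
    """
    a = np.ascontiguousarray(a, dtype=float).ravel()
    b = np.ascontiguousarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_distance requires non-empty series")
    if band is not None:
        if band < 0:
            raise ValueError("band must be >= 0")
        return _dtw_dp_banded(a, b, int(band))
    return _dtw_dp(a, b)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise DTW distance matrix with record ids attached."""

    values: np.ndarray  # (N, N)
    record_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.record_ids) != v.shape[0]:
            raise ValueError("record_ids length must match matrix size")

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    def save_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.record_ids, columns=self.record_ids).to_csv(
            path
        )

    @classmethod
    def load_csv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        frame = pd.read_csv(path, index_col=0)
        return cls(values=frame.to_numpy(dtype=float), record_ids=list(frame.index))


def distance_matrix(
    series: Sequence[np.ndarray],
    record_ids: Sequence[str] | None = None,
    band: int | None = None,
) -> DistanceMatrix:
    """Pairwise DTW distances; zero diagonal, symmetric by construction."""
    n = len(series)
    if n < 2:
        raise ValueError("distance_matrix requires at least 2 records")
    if record_ids is None:
        record_ids = [str(i) for i in range(n)]
    gamma = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(series[i], series[j], band=band)
            gamma[i, j] = gamma[j, i] = d
    return DistanceMatrix(values=gamma, record_ids=list(record_ids))


def topk_adjacency(dist: DistanceMatrix, k: int) -> np.ndarray:
    """Directed binary adjacency: row i marks the K nearest neighbours of i.

    Self-distances are excluded; ties are broken toward the smaller node
    index (stable sort), so builds are deterministic.
    """
    n = dist.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"K must satisfy 1 <= K <= N-1 = {n - 1}, got {k}")
    gamma = dist.values.astype(float).copy()
    np.fill_diagonal(gamma, np.inf)
    adjacency = np.zeros((n, n))
    for i in range(n):
        nearest = np.argsort(gamma[i], kind="stable")[:k]
        adjacency[i, nearest] = 1.0
    return adjacency


@dataclass(frozen=True)
class SRGraph:
    """Sparse relation graph with self-loops and normalized propagation matrix.

    ``adjacency`` is the raw directed top-K matrix A; ``a_tilde = A + I``;
    ``degrees`` holds the row sums of a_tilde; ``propagation`` is
    ``D^{-1/2} (A + I) D^{-1/2}``.
    """

    adjacency: np.ndarray
    k: int
    record_ids: list[str]

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all((a == 0) | (a == 1)):
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")

    @property
    def n_nodes(self) -> int:
        return int(self.adjacency.shape[0])

    @property
    def a_tilde(self) -> np.ndarray:
        return self.adjacency + np.eye(self.n_nodes)

    @property
    def degrees(self) -> np.ndarray:
        return self.a_tilde.sum(axis=1)

    @property
    def propagation(self) -> np.ndarray:
        d_inv_sqrt = 1.0 / np.sqrt(self.degrees)
        return d_inv_sqrt[:, None] * self.a_tilde * d_inv_sqrt[None, :]

    def neighborhood(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i] > 0)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lines = ["src\tdst\tweight"]
        for i, j in zip(*np.nonzero(self.adjacency)):
            lines.append(f"{self.record_ids[i]}\t{self.record_ids[j]}\t1.0")
        (directory / "edges.tsv").write_text("\n".join(lines) + "\n")
        meta = {"n_nodes": self.n_nodes, "k": self.k, "record_ids": self.record_ids,
                "normalization": "sym"}
        (directory / "graph.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "SRGraph":
        directory = Path(directory)
        meta = json.loads((directory / "graph.json").read_text())
        ids = list(meta["record_ids"])
        index = {rid: i for i, rid in enumerate(ids)}
        adjacency = np.zeros((meta["n_nodes"], meta["n_nodes"]))
        lines = (directory / "edges.tsv").read_text().strip().splitlines()[1:]
        for line in lines:
            src, dst, _ = line.split("\t")
            adjacency[index[src], index[dst]] = 1.0
        return cls(adjacency=adjacency, k=int(meta["k"]), record_ids=ids)


def build_srgraph(
    adjacency: np.ndarray, k: int, record_ids: Sequence[str] | None = None
) -> SRGraph:
    """Wrap a validated binary adjacency into an :class:`SRGraph`."""
    adjacency = np.asarray(adjacency, dtype=float)
    if record_ids is None:
        record_ids = [str(i) for i in range(adjacency.shape[0])]
    return SRGraph(adjacency=adjacency, k=int(k), record_ids=list(record_ids))


def srgraph_from_series(
    series: Sequence[np.ndarray],
    k: int,
    record_ids: Sequence[str] | None = None,
    band: int | None = None,
) -> tuple[DistanceMatrix, SRGraph]:
    """Distance matrix + graph in one step (the usual pipeline path)."""
    dist = distance_matrix(series, record_ids, band=band)
    adjacency = topk_adjacency(dist, k)
    return dist, build_srgraph(adjacency, k, dist.record_ids)
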