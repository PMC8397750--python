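"""Isomap embedding of population activity and trajectory stability.

Each (time, trial) column of the N-neuron tensor is a point in N-dimensional
state space; the cloud of all points is embedded by Isomap: a k-nearest-
neighbor graph (Euclidean edges, symmetrized by union), graph shortest-path
geodesic distances, and classical multidimensional scaling of the geodesic
matrix.  Trial and time labels are ignored during the embedding and recalled
afterwards to form per-trial trajectories, whose pairwise correlation along
each embedding dimension quantifies trajectory stability.

The circular-shuffle control destroys timing and coordination by circularly
shifting every (neuron, trial) trace independently; its embedding uses a
larger neighborhood (k = 100) because shuffled activity has much higher
intrinsic dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.neighbors import NearestNeighbors

from ringdrift._utils import pearson

logger = logging.getLogger(__name__)


@dataclass
class PointCloud:
    """Point cloud with movie-time / trial / week labels per point."""

    points: np.ndarray    # (P, D)
    time_bin: np.ndarray  # (P,)
    trial: np.ndarray     # (P,)
    week: np.ndarray      # (P,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        P = self.points.shape[0]
        for name in ("time_bin", "trial", "week"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (P,):
                raise ValueError(f"{name} must have one entry per point")
            setattr(self, name, arr)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class NeighborGraph:
    """Symmetrized k-NN graph with Euclidean edge lengths."""

    adjacency: csr_matrix  # symmetric, weights = distances
    k: int


@dataclass
class Embedding:
    """Low-dimensional coordinates plus recalled labels.

    ``kept`` indexes the points of the source cloud that survived the
    restriction to the largest connected graph component.
    """

    coords: np.ndarray       # (P', d)
    eigenvalues: np.ndarray  # (d,)
    time_bin: np.ndarray
    trial: np.ndarray
    week: np.ndarray
    kept: np.ndarray         # indices into the source cloud

    def save(self, path: str, k: int | None = None, seed: int | None = None) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=self.coords)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.create_dataset("time_bin", data=self.time_bin)
            f.create_dataset("trial", data=self.trial)
            f.create_dataset("week", data=self.week)
            f.create_dataset("kept", data=self.kept)
            f.attrs["d"] = self.coords.shape[1]
            if k is not None:
                f.attrs["k"] = k
            if seed is not None:
                f.attrs["seed"] = seed


def tensor_to_points(values: np.ndarray, week_labels: np.ndarray) -> PointCloud:
    """Flatten an (N, T, K) tensor into T*K points of dimension N."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("tensor must be finite")
    N, T, K = values.shape
    week_labels = np.asarray(week_labels, dtype=int)
    # trial-major ordering: point p = k*T + t
    points = values.transpose(2, 1, 0).reshape(T * K, N)
    trial = np.repeat(np.arange(K), T)
    time_bin = np.tile(np.arange(T), K)
    return PointCloud(
        points=points, time_bin=time_bin, trial=trial, week=week_labels[trial]
    )


def subsample_trials(
    cloud_or_tensor_trials: np.ndarray,
    week_labels: np.ndarray,
    max_points: int,
    points_per_trial: int,
    seed: int = 0,
) -> np.ndarray:
    """Choose a week-balanced subset of trials so points stay under a budget.

    Returns sorted trial indices; trials are drawn uniformly within each week
    (seeded) so that every week keeps the same number of trials.
    """
    week_labels = np.asarray(week_labels, dtype=int)
    weeks = np.unique(week_labels)
    n_keep = max(1, max_points // points_per_trial)
    per_week = max(1, n_keep // weeks.size)
    rng = np.random.default_rng(seed)
    chosen = []
    for w in weeks:
        idx = np.flatnonzero(week_labels == w)
        take = min(per_week, idx.size)
        chosen.append(rng.choice(idx, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


def knn_graph(cloud: PointCloud, k: int = 20) -> NeighborGraph:
    """Directed k-NN by Euclidean distance, symmetrized by union.

    Distance ties are broken toward the lower point index.  Duplicate points
    are allowed; the resulting zero-length edges are logged.
    """
    P = cloud.n_points
    if P <= k:
        raise ValueError("need more points than neighbors")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(cloud.points)
    dist, idx = nn.kneighbors(cloud.points)
    rows, cols, vals = [], [], []
    for i in range(P):
        # drop self; equal distances break toward the lower point index
        order = np.lexsort((idx[i], dist[i]))
        neighbors = [(d, j) for d, j in zip(dist[i][order], idx[i][order]) if j != i]
        for d, j in neighbors[:k]:
            rows.append(i)
            cols.append(j)
            vals.append(d)
    n_zero = sum(1 for v in vals if v == 0)
    if n_zero:
        logger.info("knn_graph: %d zero-length edges (duplicate points)", n_zero)
    adj = csr_matrix((vals, (rows, cols)), shape=(P, P))
    sym = adj.maximum(adj.T)  # union of directed edges, weights = distances
    return NeighborGraph(adjacency=sym, k=k)


def geodesic_distances(g: NeighborGraph) -> np.ndarray:
    """All-pairs shortest-path lengths (Dijkstra); inf across components."""
    return shortest_path(g.adjacency, method="D", directed=False)


def classical_mds(distances: np.ndarray, d: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical MDS: double-center -0.5 * J D^2 J, top-d eigenpairs.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); only positive
    eigenvalues yield coordinates (fewer than ``d`` positive eigenvalues
    returns the available dimensions with a warning).  Signs follow the
    convention that the first nonzero loading of each dimension is positive.
    """
    D = np.asarray(distances, dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite (restrict to one component)")
    P = D.shape[0]
    D2 = D**2
    B = D2 - D2.mean(axis=0, keepdims=True) - D2.mean(axis=1, keepdims=True) \
        + D2.mean()
    B *= -0.5
    B = (B + B.T) / 2
    if P <= 1200:
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1][:d]
        eigval, eigvec = eigval[order], eigvec[:, order]
    else:
        from scipy.sparse.linalg import eigsh

        # deterministic start vector: the default draws from numpy's global
        # random state, which would make embeddings run-order dependent
        v0 = np.full(P, 1.0 / np.sqrt(P))
        eigval, eigvec = eigsh(B, k=d, which="LA", v0=v0)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(abs(eigval[0]), 1.0)
    if pos.sum() < d:
        logger.warning(
            "classical_mds: only %d positive eigenvalues (requested %d)",
            int(pos.sum()), d,
        )
    eigval, eigvec = eigval[pos], eigvec[:, pos]
    coords = eigvec * np.sqrt(eigval)
    for j in range(coords.shape[1]):
        nz = np.flatnonzero(np.abs(eigvec[:, j]) > 1e-12)
        if nz.size and eigvec[nz[0], j] < 0:
            coords[:, j] *= -1
    return coords, eigval


def isomap(cloud: PointCloud, k: int = 20, d: int = 2) -> Embedding:
    """k-NN graph -> geodesics -> classical MDS on the largest component."""
    g = knn_graph(cloud, k=k)
    n_comp, labels = connected_components(g.adjacency, directed=False)
    kept = np.arange(cloud.n_points)
    adj = g.adjacency
    if n_comp > 1:
        largest = np.bincount(labels).argmax()
        kept = np.flatnonzero(labels == largest)
        logger.warning(
            "isomap: graph has %d components; keeping largest with %d/%d points",
            n_comp, kept.size, cloud.n_points,
        )
        adj = adj[kept][:, kept]
    D = shortest_path(adj, method="D", directed=False)
    coords, eigval = classical_mds(D, d=d)
    return Embedding(
        coords=coords,
        eigenvalues=eigval,
        time_bin=cloud.time_bin[kept],
        trial=cloud.trial[kept],
        week=cloud.week[kept],
        kept=kept,
    )


def circular_shuffle(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Independently circularly shift each (neuron, trial) trace in time."""
    values = np.asarray(values)
    N, T, K = values.shape
    rng = np.random.default_rng(seed)
    shifts = rng.integers(0, T, size=(N, K))
    out = np.empty_like(values)
    for n in range(N):
        for k in range(K):
            out[n, :, k] = np.roll(values[n, :, k], shifts[n, k])
    return out


def trajectory_stability(e: Embedding, min_common_bins: int = 10) -> np.ndarray:
    """Per-dimension mean Pearson CC of per-trial trajectories.

    For each embedding dimension and each unordered trial pair, the two
    trials' time-courses are correlated on their common time bins (pairs with
    fewer than ``min_common_bins`` shared bins, or constant courses, are
    skipped) and the correlations averaged.
    """
    trials = np.unique(e.trial)
    if trials.size < 2:
        raise ValueError("need at least two trials")
    d = e.coords.shape[1]
    # index per trial: time_bin -> row, for the bins this trial retains
    per_trial: list[tuple[np.ndarray, np.ndarray]] = []
    for tr in trials:
        rows = np.flatnonzero(e.trial == tr)
        order = np.argsort(e.time_bin[rows])
        per_trial.append((e.time_bin[rows][order], rows[order]))
    out = np.zeros(d)
    for dim in range(d):
        vals = []
        for i in range(trials.size):
            bins_i, rows_i = per_trial[i]
            for j in range(i + 1, trials.size):
                bins_j, rows_j = per_trial[j]
                common, ia, ja = np.intersect1d(
                    bins_i, bins_j, return_indices=True
                )
                if common.size < min_common_bins:
                    continue
                c = pearson(
                    e.coords[rows_i[ia], dim], e.coords[rows_j[ja], dim]
                )
                if np.isfinite(c):
                    vals.append(c)
        out[dim] = float(np.mean(vals)) if vals else float("nan")
    return out
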