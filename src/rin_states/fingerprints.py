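"""Closeness-centrality fingerprints of residue interaction networks.

Each frame's RIN is summarized by the N-vector of per-residue closeness
centralities

    c_i = N / sum_j d(v_i, v_j),

where d is the unweighted shortest-path length (an integer edge count) and the
sum runs over all other nodes. The scaling by the node count N (rather than
the more common N - 1) is deliberate and is the package default; a config
switch selects the standard convention. Fingerprints of a whole ensemble are
made comparable by dividing the full frames x residues matrix by its single
global maximum, mapping it into [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import DimensionError, GraphError
from .rin import ContactGraph
from .traj_io import TrajectoryEnsemble

log = logging.getLogger(__name__)


def _bfs_all_sources(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of an unweighted graph via layered BFS.

    Runs breadth-first search from every node simultaneously: the frontier of
    all sources is advanced one edge per iteration with a (BLAS-backed)
    matrix product. Returns an (N, N) int array; unreachable pairs are -1.
    """
    adj = adjacency.astype(np.float32)
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=np.int64)
    np.fill_diagonal(dist, 0)
    visited = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=np.float32)
    d = 0
    while True:
        d += 1
        reached = (frontier @ adj) > 0
        new = reached & ~visited
        if not new.any():
            break
        dist[new] = d
        visited |= new
        frontier = new.astype(np.float32)
    return dist


def shortest_path_lengths(graph: ContactGraph, source: int) -> np.ndarray:
    """BFS distances (integer edge counts) from ``source`` to every node.

    Raises GraphError naming the unreachable nodes if the graph is
    disconnected.
    """
    n = graph.n_nodes
    if not 0 <= source < n:
        raise ValueError(f"source {source} outside 0..{n - 1}")
    dist = np.full(n, -1, dtype=np.int64)
    dist[source] = 0
    frontier = [source]
    adj = graph.adjacency
    d = 0
    while frontier:
        d += 1
        reached = np.flatnonzero(adj[frontier].any(axis=0) & (dist < 0))
        dist[reached] = d
        frontier = list(reached)
    if (dist < 0).any():
        raise GraphError(
            f"graph is disconnected; unreachable from node {source}: "
            f"{np.flatnonzero(dist < 0).tolist()}")
    return dist


def closeness_fingerprint(graph: ContactGraph, convention: str = "n") -> np.ndarray:
    """Closeness centrality of every node of a connected RIN.

    ``convention="n"`` (default) computes c_i = N / sum_j d(i, j);
    ``convention="n-1"`` computes the textbook (N - 1) / sum_j d(i, j).
    The two differ only by the constant factor N / (N - 1), which cancels
    under the ensemble-wide 0-1 normalization.
    """
    n = graph.n_nodes
    if n < 2:
        raise GraphError(f"closeness needs at least 2 nodes, got {n}")
    dist = _bfs_all_sources(graph.adjacency)
    if (dist < 0).any():
        bad = np.argwhere(dist < 0)
        raise GraphError(
            f"graph is disconnected; example unreachable pair: "
            f"{tuple(int(x) for x in bad[0])}")
    sums = dist.sum(axis=1)
    if convention == "n":
        return n / sums
    if convention == "n-1":
        return (n - 1) / sums
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class FingerprintMatrix:
    """Frames x residues matrix of closeness centralities.

    ``normalized`` records whether the global 0-1 scaling has been applied;
    ``normalization_factor`` stores the global maximum used, so subsets of the
    ensemble remain on a comparable scale.
    """

    values: np.ndarray
    residue_labels: tuple
    normalized: bool = False
    normalization_factor: float | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise DimensionError(f"fingerprint matrix must be 2D, got {self.values.shape}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_residues(self) -> int:
        return self.values.shape[1]


def fingerprint_matrix(ensemble: TrajectoryEnsemble | None,
                       graphs: Sequence[ContactGraph],
                       convention: str = "n") -> FingerprintMatrix:
    """Stack the closeness fingerprints of per-frame RINs (unnormalized).

    Row f is the fingerprint of frame f; rows follow the frame order of
    ``graphs`` (which matches ``ensemble.frame_ids`` in the pipeline). The
    ensemble is optional — only residue labels are taken from it; pass None
    when working from pre-computed adjacencies.
    """
    if not graphs:
        raise ValueError("no graphs given")
    sizes = {g.n_nodes for g in graphs}
    if len(sizes) != 1:
        raise DimensionError(f"graphs have inconsistent node counts: {sorted(sizes)}")
    if ensemble is not None and len(graphs) != ensemble.n_frames:
        raise DimensionError(
            f"{len(graphs)} graphs for {ensemble.n_frames} frames")
    n = sizes.pop()
    values = np.empty((len(graphs), n))
    for f, g in enumerate(graphs):
        values[f] = closeness_fingerprint(g, convention=convention)
    if ensemble is not None and n == ensemble.topology.n_residues:
        labels = ensemble.topology.residue_labels
    else:
        labels = tuple((f"R{i}", i + 1, "A") for i in range(n))
    return FingerprintMatrix(values=values, residue_labels=labels)


def normalize_fingerprints(matrix: FingerprintMatrix) -> FingerprintMatrix:
    """Scale the whole matrix by its single global maximum into [0, 1].

    Idempotent: normalizing an already-normalized matrix returns it unchanged.
    """
    if matrix.values.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    if matrix.normalized:
        return matrix
    factor = float(matrix.values.max())
    if factor <= 0:
        raise ValueError("cannot normalize: global maximum is not positive")
    return replace(matrix, values=matrix.values / factor,
                   normalized=True, normalization_factor=factor)


# ---------------------------------------------------------------------------
# persistence

def save_fingerprints_csv(matrix: FingerprintMatrix, path) -> None:
    """CSV with residues as columns; header carries residue labels."""
    header = ",".join(f"{name}{seq}" for name, seq, _ in matrix.residue_labels)
    np.savetxt(path, matrix.values, delimiter=",", header=header, comments="")


def save_fingerprints(matrix: FingerprintMatrix, array_path, meta_path,
                      extra_meta: dict | None = None) -> None:
    """Binary array container plus JSON metadata sidecar."""
    np.save(array_path, matrix.values)
    meta = {
        "normalized": matrix.normalized,
        "normalization_factor": matrix.normalization_factor,
        "residue_labels": [list(l) for l in matrix.residue_labels],
    }
    meta.update(extra_meta or {})
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_fingerprints(array_path, meta_path) -> FingerprintMatrix:
    values = np.load(array_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    return FingerprintMatrix(
        values=values,
        residue_labels=tuple(tuple(l) for l in meta["residue_labels"]),
        normalized=meta["normalized"],
        normalization_factor=meta["normalization_factor"],
    )
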