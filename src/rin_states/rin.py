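"""Per-frame residue interaction network (RIN) construction.

A frame's RIN connects two residues if the minimum distance between their
side-chain heavy atoms falls strictly below the cutoff (default 0.45 nm), or
if they are direct sequence neighbors. The backbone rule guarantees a
connected graph for a single-chain protein, so closeness centrality is always
well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DimensionError, GraphError
from .traj_io import ResidueTopology, TrajectoryEnsemble

log = logging.getLogger(__name__)

DEFAULT_CUTOFF_NM = 0.45  # 4.5 Angstrom


@dataclass(frozen=True)
class ContactGraph:
    """Symmetric binary adjacency over residues for one frame."""

    adjacency: np.ndarray  # (N, N) bool, zero diagonal
    cutoff: float          # nm
    frame_id: tuple | None = None

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DimensionError(f"adjacency must be square, got {a.shape}")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def _atom_layout(topology: ResidueTopology, residues: Sequence[int]):
    """Flatten contact atoms of the selected residues, grouped contiguously."""
    atom_idx = np.concatenate([np.asarray(topology.contact_atoms[r], dtype=int)
                               for r in residues])
    starts = np.cumsum([0] + [len(topology.contact_atoms[r]) for r in residues[:-1]])
    return atom_idx, starts


def _min_distance_matrix(frame: np.ndarray, topology: ResidueTopology,
                         residues: Sequence[int], box: np.ndarray | None = None) -> np.ndarray:
    """Minimum side-chain heavy-atom distance for every residue pair (nm)."""
    atom_idx, starts = _atom_layout(topology, residues)
    pts = frame[atom_idx]
    if box is None:
        d = cdist(pts, pts)
    else:
        diff = pts[:, None, :] - pts[None, :, :]
        diff -= np.round(diff / box) * box  # orthorhombic minimum image
        d = np.sqrt((diff ** 2).sum(axis=-1))
    # segment-min over residue blocks: rows first, then columns
    d = np.minimum.reduceat(d, starts, axis=0)
    d = np.minimum.reduceat(d, starts, axis=1)
    return d


def min_contact_distance(frame: np.ndarray, topology: ResidueTopology,
                         i: int, j: int) -> float:
    """Minimum Euclidean distance (nm) between the contact atoms of residues i, j."""
    if i == j:
        raise ValueError(f"residue indices must differ, got i = j = {i}")
    pi = frame[list(topology.contact_atoms[i])]
    pj = frame[list(topology.contact_atoms[j])]
    return float(cdist(pi, pj).min())


def build_rin(frame: np.ndarray, topology: ResidueTopology,
              cutoff: float = DEFAULT_CUTOFF_NM, frame_id=None,
              box: np.ndarray | None = None) -> ContactGraph:
    """Build the residue interaction network of a single frame.

    ``A_ij = 1`` iff the closest side-chain distance is strictly below
    ``cutoff`` (nm) or ``(i, j)`` is a backbone pair.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    residues = range(topology.n_residues)
    d = _min_distance_matrix(frame, topology, list(residues), box=box)
    adj = d < cutoff
    np.fill_diagonal(adj, False)
    for i, j in topology.backbone_pairs:
        adj[i, j] = adj[j, i] = True
    return ContactGraph(adjacency=adj, cutoff=cutoff, frame_id=frame_id)


def build_rin_subset(frame: np.ndarray, topology: ResidueTopology,
                     residue_range: tuple[int, int],
                     cutoff: float = DEFAULT_CUTOFF_NM, frame_id=None,
                     box: np.ndarray | None = None) -> ContactGraph:
    """RIN restricted to an inclusive residue index interval.

    Contacts to residues outside the interval are ignored entirely, matching
    an isolated-domain analysis; backbone pairs inside the interval remain.
    """
    lo, hi = residue_range
    if hi - lo + 1 < 2:
        raise ValueError(f"residue range must contain at least 2 residues, got {residue_range}")
    if lo < 0 or hi >= topology.n_residues:
        raise ValueError(f"residue range {residue_range} outside 0..{topology.n_residues - 1}")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    residues = list(range(lo, hi + 1))
    d = _min_distance_matrix(frame, topology, residues, box=box)
    adj = d < cutoff
    np.fill_diagonal(adj, False)
    for i, j in topology.backbone_pairs:
        if lo <= i and j <= hi:
            adj[i - lo, j - lo] = adj[j - lo, i - lo] = True
    return ContactGraph(adjacency=adj, cutoff=cutoff, frame_id=frame_id)


def build_rins(ensemble: TrajectoryEnsemble, cutoff: float = DEFAULT_CUTOFF_NM,
               residue_range: tuple[int, int] | None = None,
               box: np.ndarray | None = None) -> list[ContactGraph]:
    """Build one ContactGraph per frame of an ensemble.

    Frames are processed independently, so results do not depend on how the
    ensemble was batched or ordered.
    """
    graphs = []
    for f in range(ensemble.n_frames):
        frame = ensemble.frames[f]
        fid = ensemble.frame_ids[f]
        if residue_range is None:
            graphs.append(build_rin(frame, ensemble.topology, cutoff, frame_id=fid, box=box))
        else:
            graphs.append(build_rin_subset(frame, ensemble.topology, residue_range,
                                           cutoff, frame_id=fid, box=box))
    log.info("built %d RINs (N=%d, cutoff=%.3f nm)", len(graphs),
             graphs[0].n_nodes if graphs else 0, cutoff)
    return graphs


def adjacency_stack(graphs: Sequence[ContactGraph]) -> np.ndarray:
    """Stack per-frame adjacencies into an (F, N, N) boolean array."""
    n = {g.n_nodes for g in graphs}
    if len(n) != 1:
        raise DimensionError(f"graphs have inconsistent node counts: {sorted(n)}")
    return np.stack([g.adjacency for g in graphs])


def assert_connected(graph: ContactGraph) -> None:
    """Raise GraphError naming unreachable nodes if the graph is disconnected."""
    from .fingerprints import _bfs_all_sources

    dist = _bfs_all_sources(graph.adjacency)
    unreachable = np.argwhere(dist[0] < 0).ravel()
    if unreachable.size:
        raise GraphError(f"graph is disconnected; nodes unreachable from node 0: "
                         f"{unreachable.tolist()}")


# ---------------------------------------------------------------------------
# text exports

def export_adjacency_csv(graph: ContactGraph, path) -> None:
    """Write the dense 0/1 adjacency matrix as CSV."""
    np.savetxt(path, graph.adjacency.astype(int), fmt="%d", delimiter=",")


def export_edge_list(graph: ContactGraph, path) -> None:
    """Write an ``i,j`` edge list (upper triangle, 0-based indices)."""
    ij = np.argwhere(np.triu(graph.adjacency, 1))
    with open(path, "w") as fh:
        fh.write("i,j\n")
        for i, j in ij:
            fh.write(f"{i},{j}\n")


def export_contact_table(graphs: Sequence[ContactGraph], path) -> None:
    """Write a frames x residue-pairs boolean table (upper-triangle pairs)."""
    stack = adjacency_stack(graphs)
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, 1)
    table = stack[:, iu, ju].astype(int)
    header = ",".join(f"{i}-{j}" for i, j in zip(iu, ju))
    np.savetxt(path, table, fmt="%d", delimiter=",", header=header, comments="")
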