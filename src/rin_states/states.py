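"""State-specific characterization of landscape clusters.

Each density cluster (residue interaction state) is characterized at every
level of the upstream workflow: its population, its mean closeness
fingerprint, its consensus contact graph (per-edge occurrence probability),
contrasts between states as difference graphs, and representative frames
(evenly spaced members, density exemplars, and a fingerprint centroid).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DimensionError
from .fingerprints import FingerprintMatrix
from .landscape import ClusterLabels, LandscapeEmbedding
from .rin import ContactGraph, adjacency_stack
from .traj_io import ResidueTopology

log = logging.getLogger(__name__)

#: probability bins used to display consensus-graph edges
EDGE_BINS = ((0.25, 0.50, "low"), (0.50, 0.75, "mid"), (0.75, 1.0 + 1e-12, "high"))


@dataclass(frozen=True)
class ConsensusGraph:
    """Per-contact occurrence probabilities within one cluster."""

    weights: np.ndarray     # (N, N) in [0, 1], symmetric, zero diagonal
    cluster_id: int
    n_members: int
    bins: tuple = EDGE_BINS

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class DifferenceGraph:
    """Elementwise difference of two consensus graphs (A minus B)."""

    weights: np.ndarray     # (N, N) in [-1, 1], antisymmetric under swap
    cluster_pair: tuple[int, int]
    display_threshold: float = 0.5


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    population_fraction: float
    mean_fingerprint: np.ndarray
    representatives: tuple
    exemplars: tuple
    centroid: object


@dataclass(frozen=True)
class MapColoring:
    """A per-frame scalar used to color the landscape."""

    kind: str               # density | rg | residue_closeness | contact_probability | interface_score | cluster_id
    values: np.ndarray
    metadata: dict = field(default_factory=dict)


def cluster_populations(labels: ClusterLabels) -> dict[int, float]:
    """Population fraction of every cluster; noise reported under key -1.

    Fractions over all clusters plus noise sum to 1 exactly.
    """
    lab = labels.labels
    if lab.size == 0:
        raise ValueError("labels are empty")
    total = lab.size
    out = {c: int((lab == c).sum()) / total for c in labels.cluster_ids}
    out[-1] = int((lab == -1).sum()) / total
    return out


def _member_rows(labels: ClusterLabels, cluster_id: int) -> np.ndarray:
    rows = np.flatnonzero(labels.labels == cluster_id)
    if rows.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty or unknown")
    return rows


def mean_fingerprint(matrix: FingerprintMatrix, labels: ClusterLabels,
                     cluster_id: int) -> np.ndarray:
    """Column-wise mean closeness over the cluster's member frames."""
    if matrix.n_frames != labels.n_frames:
        raise DimensionError(f"{matrix.n_frames} fingerprints vs {labels.n_frames} labels")
    rows = _member_rows(labels, cluster_id)
    return matrix.values[rows].mean(axis=0)


def consensus_graph(graphs: Sequence[ContactGraph], labels: ClusterLabels,
                    cluster_id: int) -> ConsensusGraph:
    """Mean adjacency over cluster members: per-contact probabilities.

    Backbone edges are present in every frame, so their weight is exactly 1.
    """
    if len(graphs) != labels.n_frames:
        raise DimensionError(f"{len(graphs)} graphs vs {labels.n_frames} labels")
    rows = _member_rows(labels, cluster_id)
    stack = adjacency_stack(graphs)
    weights = stack[rows].mean(axis=0)
    return ConsensusGraph(weights=weights, cluster_id=cluster_id, n_members=rows.size)


def bin_edge_weights(consensus: ConsensusGraph) -> dict[tuple[int, int], str]:
    """Display category for every upper-triangle edge with weight >= 0.25.

    Categories: [0.25, 0.50) low, [0.50, 0.75) mid, [0.75, 1] high; weights
    below 0.25 are not displayed (absent from the result).
    """
    out: dict[tuple[int, int], str] = {}
    n = consensus.n_nodes
    iu, ju = np.triu_indices(n, 1)
    w = consensus.weights[iu, ju]
    for i, j, wij in zip(iu, ju, w):
        for lo, hi, name in consensus.bins:
            if lo <= wij < hi:
                out[(int(i), int(j))] = name
                break
    return out


def difference_graph(consensus_a: ConsensusGraph, consensus_b: ConsensusGraph,
                     display_threshold: float = 0.5) -> DifferenceGraph:
    """Contact-probability difference A - B; arcs drawn for |w| > threshold."""
    if consensus_a.weights.shape != consensus_b.weights.shape:
        raise DimensionError(
            f"consensus shapes differ: {consensus_a.weights.shape} vs "
            f"{consensus_b.weights.shape}")
    return DifferenceGraph(
        weights=consensus_a.weights - consensus_b.weights,
        cluster_pair=(consensus_a.cluster_id, consensus_b.cluster_id),
        display_threshold=display_threshold,
    )


def contact_probability_series(graphs: Sequence[ContactGraph],
                               contact: tuple[int, int]) -> MapColoring:
    """Per-frame 0/1 indicator of one residue contact, for landscape coloring."""
    i, j = contact
    n = graphs[0].n_nodes
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"contact {contact} outside 0..{n - 1}")
    values = np.array([float(g.adjacency[i, j]) for g in graphs])
    return MapColoring(kind="contact_probability", values=values,
                       metadata={"contact": (int(i), int(j))})


def radius_of_gyration(frame: np.ndarray, atom_selection: Sequence[int],
                       masses: Sequence[float] | None = None) -> float:
    """Mass-weighted RMS distance of the selected atoms from their center of mass (nm)."""
    sel = np.asarray(atom_selection, dtype=int)
    if sel.size == 0:
        raise ValueError("atom selection is empty")
    pts = frame[sel]
    if masses is None:
        w = np.ones(sel.size)
    else:
        w = np.asarray(masses, dtype=float)[sel]
    w = w / w.sum()
    com = (w[:, None] * pts).sum(axis=0)
    return float(np.sqrt((w * ((pts - com) ** 2).sum(axis=1)).sum()))


def rg_series(frames: np.ndarray, topology: ResidueTopology,
              heavy_only: bool = True) -> MapColoring:
    """Radius of gyration of every frame, over protein heavy atoms by default."""
    masses = np.asarray(topology.masses) if topology.masses else np.ones(topology.n_atoms)
    if heavy_only:
        sel = np.flatnonzero(masses > 2.0)  # excludes hydrogen/massless
        if sel.size == 0:
            sel = np.arange(topology.n_atoms)
    else:
        sel = np.arange(topology.n_atoms)
    values = np.array([radius_of_gyration(f, sel, masses) for f in frames])
    return MapColoring(kind="rg", values=values, metadata={"n_atoms": int(sel.size)})


def interface_score(graph: ContactGraph, split: int,
                    domain_nd: tuple[int, int], domain_cd: tuple[int, int]) -> int:
    """Signed count of cross-domain contacts.

    Contacts between the first section of the N-terminal domain (indices
    <= split) and the C-terminal domain count +1; contacts between the second
    section (> split) and the C-terminal domain count -1. Backbone pairs lie
    within one domain and never contribute.
    """
    nd_lo, nd_hi = domain_nd
    cd_lo, cd_hi = domain_cd
    if not (nd_lo <= split <= nd_hi):
        raise ValueError(f"split {split} outside ND interval {domain_nd}")
    if max(nd_lo, cd_lo) <= min(nd_hi, cd_hi):
        raise ValueError(f"domains {domain_nd} and {domain_cd} overlap")
    adj = graph.adjacency
    cd = slice(cd_lo, cd_hi + 1)
    pos = int(adj[nd_lo:split + 1, cd].sum())
    neg = int(adj[split + 1:nd_hi + 1, cd].sum())
    return pos - neg


def interface_score_series(graphs: Sequence[ContactGraph], split: int,
                           domain_nd: tuple[int, int],
                           domain_cd: tuple[int, int]) -> MapColoring:
    values = np.array([interface_score(g, split, domain_nd, domain_cd)
                       for g in graphs], dtype=float)
    return MapColoring(kind="interface_score", values=values,
                       metadata={"split": split, "domain_nd": domain_nd,
                                 "domain_cd": domain_cd})


def select_evenly_spaced(members: Sequence, n: int = 10) -> list:
    """n members evenly spaced along the ordered member list.

    First and last members are always included for M >= n; returns all
    members when the list is shorter than n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    members = list(members)
    if not members:
        raise ValueError("member list is empty")
    m = len(members)
    if m <= n:
        return members
    if n == 1:
        return [members[0]]
    idx = np.round(np.arange(n) * (m - 1) / (n - 1)).astype(int)
    return [members[i] for i in idx]


def select_exemplars(labels: ClusterLabels, embedding: LandscapeEmbedding,
                     cluster_id: int, n: int = 10,
                     exemplar_indices: Sequence[int] | None = None,
                     k_density: int = 15) -> list[int]:
    """Up to n exemplar frames for a cluster, reduced by even spacing.

    If the clustering backend supplies exemplar points, pass their frame
    indices via ``exemplar_indices`` and they are reduced with the evenly-
    spaced rule. Otherwise the cluster's densest members in the embedding —
    smallest mean distance to their ``k_density`` nearest within-cluster
    neighbors — stand in for the backend's dense-core exemplars.
    """
    rows = _member_rows(labels, cluster_id)
    if exemplar_indices is not None:
        ex = [int(i) for i in exemplar_indices if labels.labels[i] == cluster_id]
        return select_evenly_spaced(ex, n)
    pts = embedding.coords[rows]
    k = min(k_density + 1, rows.size)
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k).fit(pts)
    dist, _ = nn.kneighbors(pts)
    local = dist[:, 1:].mean(axis=1) if k > 1 else np.zeros(rows.size)
    # densest core: take the top ~10% (at least n) and keep frame order
    n_core = max(n, int(np.ceil(0.1 * rows.size)))
    core = np.sort(rows[np.argsort(local, kind="stable")[:n_core]])
    return select_evenly_spaced([int(i) for i in core], n)


def select_centroid(exemplars: Sequence[int], matrix: FingerprintMatrix) -> int:
    """The exemplar closest to all others in fingerprint space.

    Minimizes the summed Euclidean distance to the other exemplars; ties are
    broken by the lowest frame index.
    """
    ex = [int(i) for i in exemplars]
    if not ex:
        raise ValueError("exemplar list is empty")
    pts = matrix.values[ex]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    sums = d.sum(axis=1)
    order = np.lexsort((ex, sums))  # by sum, then by frame index
    return ex[order[0]]


def summarize_cluster(cluster_id: int, matrix: FingerprintMatrix,
                      labels: ClusterLabels, embedding: LandscapeEmbedding,
                      n_representatives: int = 10) -> ClusterSummary:
    """Bundle population, mean fingerprint, and representative selections."""
    pops = cluster_populations(labels)
    members = [int(i) for i in _member_rows(labels, cluster_id)]
    reps = select_evenly_spaced(members, n_representatives)
    ex = select_exemplars(labels, embedding, cluster_id, n_representatives)
    centroid = select_centroid(ex, matrix)
    return ClusterSummary(
        cluster_id=cluster_id,
        population_fraction=pops[cluster_id],
        mean_fingerprint=mean_fingerprint(matrix, labels, cluster_id),
        representatives=tuple(reps),
        exemplars=tuple(ex),
        centroid=centroid,
    )


# ---------------------------------------------------------------------------
# text exports

def save_summary_json(summary: ClusterSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "cluster_id": summary.cluster_id,
            "population_fraction": summary.population_fraction,
            "mean_fingerprint": summary.mean_fingerprint.tolist(),
            "representatives": list(summary.representatives),
            "exemplars": list(summary.exemplars),
            "centroid": summary.centroid,
        }, fh, indent=2)


def save_weight_matrix_csv(weights: np.ndarray, path) -> None:
    np.savetxt(path, weights, delimiter=",", fmt="%.6f")


def save_edge_list_csv(graph: ConsensusGraph | DifferenceGraph, path) -> None:
    """Edge list ``i,j,weight,category`` (consensus bins or difference sign)."""
    w = graph.weights
    iu, ju = np.triu_indices(w.shape[0], 1)
    with open(path, "w") as fh:
        fh.write("i,j,weight,category\n")
        if isinstance(graph, ConsensusGraph):
            cats = bin_edge_weights(graph)
            for (i, j), cat in sorted(cats.items()):
                fh.write(f"{i},{j},{w[i, j]:.6f},{cat}\n")
        else:
            for i, j in zip(iu, ju):
                if abs(w[i, j]) > graph.display_threshold:
                    sign = "gain" if w[i, j] > 0 else "loss"
                    fh.write(f"{i},{j},{w[i, j]:.6f},{sign}\n")
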