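"""Rendering of residue interaction landscapes and arc diagrams.

Landscape maps are 2D scatter plots colored by any per-frame scalar (log
density, radius of gyration, per-residue closeness, contact probability,
interface score, or cluster id), optionally overlaid with kernel-density
cluster outlines. Consensus and difference graphs are drawn as arc diagrams:
residues on a line, colored by a per-residue value (typically the cluster's
mean closeness fingerprint), with arcs styled by probability bin or by sign.

SVG is the default output format (deterministic vector output); PNG is
available through the file extension.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "rin-states"  # deterministic SVG ids
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.path import Path as MplPath
from matplotlib.patches import PathPatch

from .errors import DimensionError
from .landscape import ClusterLabels, LandscapeEmbedding, landscape_density
from .states import ConsensusGraph, DifferenceGraph, MapColoring, bin_edge_weights

log = logging.getLogger(__name__)

_ARC_STYLES = {"low": (0.8, "0.7"), "mid": (1.4, "0.45"), "high": (2.2, "0.1")}


def render_landscape(embedding: LandscapeEmbedding, coloring: MapColoring,
                     outlines: ClusterLabels | None = None, path=None,
                     bins: int = 200, outline_bandwidth: float | None = None,
                     title: str | None = None):
    """Scatter the 2D landscape colored by a per-frame scalar.

    ``density`` colorings are shown on a log scale; ``cluster_id`` colorings
    get one discrete legend entry per cluster plus noise. Optional cluster
    outlines are drawn as kernel-density contours per cluster.
    """
    if coloring.values.shape[0] != embedding.n_frames:
        raise DimensionError(
            f"coloring length {coloring.values.shape[0]} does not match "
            f"{embedding.n_frames} frames")
    xy = embedding.coords[:, :2]
    fig, ax = plt.subplots(figsize=(6, 5))
    if coloring.kind == "cluster_id":
        labels = coloring.values.astype(int)
        cmap = plt.get_cmap("tab10")
        for c in sorted(np.unique(labels)):
            m = labels == c
            color = "0.7" if c == -1 else cmap(c % 10)
            name = "noise" if c == -1 else f"cluster {c}"
            ax.scatter(xy[m, 0], xy[m, 1], s=3, color=color, label=name, rasterized=False)
        ax.legend(markerscale=3, fontsize=8)
    else:
        values = coloring.values
        if coloring.kind == "density":
            values = landscape_density(embedding, bins=bins)
            label = "log10(density)"
        else:
            label = coloring.kind
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, s=3, cmap="viridis")
        fig.colorbar(sc, ax=ax, label=label)
    if outlines is not None:
        _draw_outlines(ax, xy, outlines, bandwidth=outline_bandwidth)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, metadata=_deterministic_metadata(path))
        plt.close(fig)
        log.info("wrote landscape to %s", path)
        return path
    return fig


def _deterministic_metadata(path) -> dict:
    """Strip timestamps so identical inputs give identical files."""
    p = str(path)
    if p.endswith(".svg"):
        return {"Date": None}
    if p.endswith(".png"):
        return {"Software": None}
    return {}


def _draw_outlines(ax, xy, outlines: ClusterLabels, bandwidth: float | None) -> None:
    from scipy.stats import gaussian_kde

    gx = np.linspace(xy[:, 0].min(), xy[:, 0].max(), 120)
    gy = np.linspace(xy[:, 1].min(), xy[:, 1].max(), 120)
    gxx, gyy = np.meshgrid(gx, gy)
    grid = np.vstack([gxx.ravel(), gyy.ravel()])
    for c in outlines.cluster_ids:
        pts = xy[outlines.labels == c]
        if pts.shape[0] < 3 or np.allclose(pts.std(axis=0), 0):
            continue
        try:
            kde = gaussian_kde(pts.T, bw_method=bandwidth)
        except np.linalg.LinAlgError:
            continue
        z = kde(grid).reshape(gxx.shape)
        ax.contour(gxx, gyy, z, levels=[z.max() * 0.1], colors="k", linewidths=0.8)


def render_arc_diagram(graph: ConsensusGraph | DifferenceGraph,
                       node_values: np.ndarray, mask=None, path=None,
                       title: str | None = None):
    """Arc diagram of a consensus or difference graph.

    Residues lie on a horizontal line as tiles colored by ``node_values``
    (e.g. the cluster's mean closeness fingerprint). Consensus arcs are
    styled by probability bin (low/mid/high); difference arcs by sign
    (gain vs loss), drawn only where |weight| exceeds the display threshold.
    ``mask`` is an optional sequence of index-interval pairs
    ``((lo1, hi1), (lo2, hi2))``; an edge is kept only if it connects the two
    intervals of at least one pair (e.g. to omit intradomain contacts).
    """
    w = graph.weights
    n = w.shape[0]
    node_values = np.asarray(node_values)
    if node_values.shape[0] != n:
        raise DimensionError(f"node_values length {node_values.shape[0]} != {n} residues")

    if isinstance(graph, ConsensusGraph):
        arcs = [(i, j, w[i, j], cat) for (i, j), cat in bin_edge_weights(graph).items()]
    else:
        iu, ju = np.triu_indices(n, 1)
        arcs = [(int(i), int(j), w[i, j], "gain" if w[i, j] > 0 else "loss")
                for i, j in zip(iu, ju) if abs(w[i, j]) > graph.display_threshold]
    if mask is not None:
        arcs = [a for a in arcs if _crosses_mask(a[0], a[1], mask)]

    fig, ax = plt.subplots(figsize=(9, 4))
    sc = ax.scatter(np.arange(n), np.zeros(n), c=node_values, cmap="viridis",
                    marker="s", s=18, zorder=3)
    fig.colorbar(sc, ax=ax, label="node value", fraction=0.04)
    for i, j, wij, cat in arcs:
        if cat in _ARC_STYLES:
            lw, color = _ARC_STYLES[cat]
        else:
            lw, color = 1.6, ("tab:red" if cat == "gain" else "tab:blue")
        _arc(ax, i, j, lw=lw, color=color)
    ax.set_ylim(-0.5, n / 3.5)
    ax.set_xlabel("residue index")
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, metadata=_deterministic_metadata(path))
        plt.close(fig)
        log.info("wrote arc diagram with %d arcs to %s", len(arcs), path)
        return path
    return fig


def _crosses_mask(i: int, j: int, mask) -> bool:
    for (lo1, hi1), (lo2, hi2) in mask:
        if (lo1 <= i <= hi1 and lo2 <= j <= hi2) or (lo1 <= j <= hi1 and lo2 <= i <= hi2):
            return True
    return False


def _arc(ax, i: int, j: int, lw: float, color) -> None:
    mid = (i + j) / 2.0
    height = abs(j - i) / 2.0
    path = MplPath([(i, 0), (mid, 1.4 * height), (j, 0)],
                   [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3])
    ax.add_patch(PathPatch(path, fill=False, lw=lw, edgecolor=color, zorder=2))
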