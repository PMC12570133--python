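"""Low-dimensional residue interaction landscapes and density clustering.

The normalized fingerprint matrix (frames x residues) is embedded into a 2D
map. PCA gives the global, linear view; a small autoencoder trained with a
sketch-map sigmoid pairwise-distance cost gives a nonlinear, multidimensional-
scaling-like view; UMAP (delegated to umap-learn) emphasizes local
neighborhood structure. Dense regions of the map are turned into discrete
states with HDBSCAN; frames outside any dense region are labeled -1 (noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CapabilityError, DimensionError
from .fingerprints import FingerprintMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the sketch-map sigmoid s(r).

    ``sigma`` is the distance scale at which s = 0.5; ``a`` and ``b`` control
    the steepness below and above sigma. Defaults are the high-dimensional
    set used for closeness fingerprints; the matching low-dimensional set is
    (1, 2, 6).
    """

    sigma: float = 1.1
    a: float = 6.0
    b: float = 6.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError(f"sigmoid parameters must be strictly positive: {self}")


#: Table of sigmoid defaults: high-dim (fingerprint space) and low-dim (map space)
SIGMOID_HIGH = SigmoidParams(sigma=1.1, a=6.0, b=6.0)
SIGMOID_LOW = SigmoidParams(sigma=1.0, a=2.0, b=6.0)


@dataclass(frozen=True)
class LandscapeEmbedding:
    """Low-dimensional coordinates of every frame."""

    coords: np.ndarray                 # (F, k)
    method: str                        # pca | encodermap-like | umap | external
    explained_variance: np.ndarray | None = None  # pca only
    params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class ClusterLabels:
    """Per-frame state assignment; -1 marks noise frames."""

    labels: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels) if c >= 0)


def sketchmap_sigmoid(r, p: SigmoidParams):
    """Sketch-map sigmoid s(r) = 1 - (1 + (2^(a/b) - 1) (r/sigma)^a)^(-b/a).

    Maps distances to [0, 1): s(0) = 0, s(sigma) = 1/2, monotone increasing.
    Accepts scalars or arrays; raises on negative input.
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("distances must be non-negative")
    c = 2.0 ** (p.a / p.b) - 1.0
    out = 1.0 - (1.0 + c * (r / p.sigma) ** p.a) ** (-p.b / p.a)
    return float(out) if out.ndim == 0 else out


def _sigmoid_derivative(r: np.ndarray, p: SigmoidParams) -> np.ndarray:
    """ds/dr of the sketch-map sigmoid (0 at r = 0 for a > 1)."""
    c = 2.0 ** (p.a / p.b) - 1.0
    x = r / p.sigma
    inner = 1.0 + c * x ** p.a
    return p.b * c * x ** (p.a - 1.0) / p.sigma * inner ** (-p.b / p.a - 1.0)


def pca_embed(matrix: FingerprintMatrix, k: int = 2) -> LandscapeEmbedding:
    """Project mean-centered fingerprints onto the top-k principal components."""
    from sklearn.decomposition import PCA

    x = matrix.values
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames")
    if k > min(x.shape):
        raise ValueError(f"k={k} exceeds min(F, N) = {min(x.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    return LandscapeEmbedding(
        coords=coords, method="pca",
        explained_variance=pca.explained_variance_ratio_.copy(),
        params={"k": k},
    )


class _MLP:
    """Minimal fully-connected net with tanh hidden layers (numpy, CPU)."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray):
        acts = [x]
        n = len(self.W)
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = acts[-1] @ w + b
            acts.append(np.tanh(z) if i < n - 1 else z)  # last layer linear
        return acts

    def backward(self, acts, grad_out: np.ndarray, l2: float):
        """Return (param grads, grad wrt input)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = grad_out
        for i in reversed(range(len(self.W))):
            if i < len(self.W) - 1:
                g = g * (1.0 - acts[i + 1] ** 2)  # tanh'
            gW[i] = acts[i].T @ g + l2 * self.W[i]
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return gW, gb, g

    @property
    def params(self):
        return self.W + self.b


def _pairwise_dist(x: np.ndarray) -> np.ndarray:
    d2 = np.maximum(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1), 0.0)
    return np.sqrt(d2)


def embed_nonlinear(matrix: FingerprintMatrix, method: str = "encodermap-like",
                    params: dict | None = None, seed: int = 0) -> LandscapeEmbedding:
    """Nonlinear 2D embedding of the fingerprint matrix.

    ``encodermap-like``: a small feed-forward autoencoder whose loss is the
    reconstruction error plus the mean squared mismatch between sigmoid-
    transformed pairwise distances in fingerprint space and in map space
    (high-dim and low-dim sigmoids parameterized separately). Deterministic
    for a fixed seed. ``umap``: delegates to umap-learn with a fixed
    random_state.
    """
    params = dict(params or {})
    x = matrix.values
    if method == "umap":
        try:
            import umap
        except Exception as exc:  # noqa: BLE001
            raise CapabilityError(
                "umap backend unavailable; installed methods: pca, encodermap-like"
            ) from exc
        k = params.pop("k", 2)
        reducer = umap.UMAP(n_components=k, random_state=seed, **params)
        coords = np.asarray(reducer.fit_transform(x), dtype=np.float64)
        return LandscapeEmbedding(coords=coords, method="umap",
                                  params={"k": k, "seed": seed, **params})
    if method != "encodermap-like":
        raise CapabilityError(
            f"unknown method {method!r}; installed methods: pca, encodermap-like, umap")

    k = params.get("k", 2)
    hidden = params.get("hidden", [128, 128])
    n_steps = params.get("n_steps", 300)
    batch = params.get("batch", 256)
    lr = params.get("lr", 1e-3)
    l2 = params.get("regularization", 1e-5)
    dist_weight = params.get("dist_weight", 1.0)
    sig_h = params.get("sigmoid_high", SIGMOID_HIGH)
    sig_l = params.get("sigmoid_low", SIGMOID_LOW)

    rng = np.random.default_rng(seed)
    n_features = x.shape[1]
    encoder = _MLP([n_features, *hidden, k], rng)
    decoder = _MLP([k, *hidden[::-1], n_features], rng)

    # Adam state
    all_params = encoder.params + decoder.params
    m = [np.zeros_like(p) for p in all_params]
    v = [np.zeros_like(p) for p in all_params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    f = x.shape[0]
    for step in range(1, n_steps + 1):
        idx = rng.choice(f, size=min(batch, f), replace=False)
        xb = x[idx]
        nb = xb.shape[0]

        enc_acts = encoder.forward(xb)
        z = enc_acts[-1]
        dec_acts = decoder.forward(z)
        out = dec_acts[-1]

        # reconstruction gradient
        grad_out = 2.0 * (out - xb) / (nb * n_features)
        dec_gW, dec_gb, grad_z = decoder.backward(dec_acts, grad_out, l2)

        # sigmoid pairwise-distance cost gradient wrt z
        rh = _pairwise_dist(xb)
        rl = _pairwise_dist(z)
        sh = sketchmap_sigmoid(rh, sig_h)
        sl = sketchmap_sigmoid(rl, sig_l)
        n_pairs = nb * (nb - 1)
        diff = sl - sh
        with np.errstate(divide="ignore", invalid="ignore"):
            coef = 2.0 * diff * _sigmoid_derivative(rl, sig_l) / np.maximum(rl, 1e-12)
        np.fill_diagonal(coef, 0.0)
        coef *= dist_weight / n_pairs
        grad_z_dist = 2.0 * (coef.sum(axis=1, keepdims=True) * z - coef @ z)

        enc_gW, enc_gb, _ = encoder.backward(enc_acts, grad_z + grad_z_dist, l2)

        grads = enc_gW + enc_gb + dec_gW + dec_gb
        for p, g, mi, vi in zip(all_params, grads, m, v):
            mi *= beta1
            mi += (1 - beta1) * g
            vi *= beta2
            vi += (1 - beta2) * g * g
            mhat = mi / (1 - beta1 ** step)
            vhat = vi / (1 - beta2 ** step)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    coords = encoder.forward(x)[-1]
    return LandscapeEmbedding(
        coords=coords, method="encodermap-like",
        params={"k": k, "hidden": hidden, "n_steps": n_steps, "batch": batch,
                "lr": lr, "regularization": l2, "dist_weight": dist_weight,
                "sigmoid_high": sig_h, "sigmoid_low": sig_l, "seed": seed},
    )


def cluster_density(embedding: LandscapeEmbedding, min_cluster_size: int = 100,
                    min_samples: int | None = None,
                    selection: str = "eom") -> ClusterLabels:
    """HDBSCAN density clustering of the landscape coordinates.

    Cluster ids are relabeled to 0..K-1 in order of decreasing population;
    noise stays -1. The parameters are recorded verbatim in ``params``.
    """
    from sklearn.cluster import HDBSCAN

    coords = embedding.coords
    if coords.shape[0] == 0:
        raise ValueError("embedding is empty")
    if min_cluster_size < 2:
        raise ValueError(f"min_cluster_size must be >= 2, got {min_cluster_size}")
    if selection not in ("eom", "leaf"):
        raise ValueError(f"selection must be 'eom' or 'leaf', got {selection!r}")

    params = {"min_cluster_size": min_cluster_size, "min_samples": min_samples,
              "cluster_selection_method": selection}

    # degenerate density: all points coincide -> one cluster, no noise
    if np.allclose(coords, coords[0]):
        return ClusterLabels(labels=np.zeros(coords.shape[0], dtype=int), params=params)

    clusterer = HDBSCAN(min_cluster_size=min_cluster_size, min_samples=min_samples,
                        cluster_selection_method=selection, allow_single_cluster=True,
                        copy=True)
    raw = clusterer.fit_predict(coords)
    labels = _relabel_by_population(raw)
    k = labels.max() + 1 if labels.size else 0
    log.info("HDBSCAN: %d clusters, %.1f%% classified",
             k, 100.0 * (labels >= 0).mean())
    return ClusterLabels(labels=labels, params=params)


def _relabel_by_population(raw: np.ndarray) -> np.ndarray:
    """Map raw cluster ids to contiguous 0..K-1 by decreasing size; keep -1."""
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    mapping = {int(old): new for new, old in enumerate(order)}
    out = np.full_like(raw, -1)
    for old, new in mapping.items():
        out[raw == old] = new
    return out


def landscape_density(embedding: LandscapeEmbedding, bins: int = 200) -> np.ndarray:
    """Per-frame log10 density from a 2D histogram of the first two coordinates.

    Used for the log(density) coloring of landscape maps; empty-bin artifacts
    are avoided because every frame sits in an occupied bin.
    """
    xy = embedding.coords[:, :2]
    h, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins)
    ix = np.clip(np.searchsorted(xe, xy[:, 0], side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, xy[:, 1], side="right") - 1, 0, bins - 1)
    return np.log10(h[ix, iy])
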