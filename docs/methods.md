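# Methods

## RIN construction

Every frame is converted into an unweighted, undirected residue interaction
network. The contact criterion is geometric: residues $i \ne j$ are connected
iff the minimum Euclidean distance over all pairs of their *contact atoms*
falls **strictly below** the cutoff (default 4.5 Å; the inequality is strict
because the criterion is stated as "below" the cutoff), or iff they are
direct sequence neighbors in the same chain. Contact atoms are side-chain
heavy atoms; residues without any (glycine) fall back to their α-carbon (a
config flag switches the fallback to all backbone heavy atoms). Backbone
edges guarantee that any single-chain protein yields a connected graph, so
closeness centrality is always well defined. Chain breaks are detected both
by chain identifier and by a discontinuity in residue numbering; no backbone
edge crosses a break.

Distances are computed without periodic imaging by default (trajectories are
assumed whole-molecule); an orthorhombic minimum-image correction can be
enabled by passing box vectors. Internally all lengths are nm; user-facing
cutoffs are accepted in Å and converted once. Residues are indexed 0-based
internally while reports carry the file's residue numbers.

An isolated-domain analysis (`build_rin_subset`) restricts the graph to an
inclusive residue interval and discards every contact to residues outside
it, retaining backbone edges inside the interval.

## Closeness fingerprint

For each frame's graph, closeness is computed for every node as
$c_i = N / \sum_j d(v_i, v_j)$ with integer shortest-path lengths from
breadth-first search. The scaling by $N$ rather than the textbook $N-1$
is deliberate: it is the form the fingerprint is defined with, and the
constant factor cancels under the global normalization anyway; a
`convention="n-1"` switch selects the standard form (which then agrees with
networkx's `closeness_centrality`). Distances are obtained by running BFS
from all sources simultaneously — the combined frontier is advanced one edge
per iteration with a BLAS matrix product — which is exact for integer
distances and fast at typical protein sizes ($N$ of order 100–200).

The frames × residues matrix is normalized by dividing by its single global
maximum, computed over the whole ensemble in one pass and stored in the
output metadata (`normalization_factor`) so that subsets remain on a
comparable scale. Normalization is idempotent. When a subset of residues is
analyzed in isolation, the maximum is recomputed on that analysis's own
matrix: normalization is per-analysis.

## Landscape embedding

**PCA** (scikit-learn, full SVD) is the default global view; the first two
components are used for the map, and clustering may optionally run on more
components. **The autoencoder embedder** is a small numpy feed-forward
network (default hidden layers 128–128, linear 2D bottleneck, tanh
activations, Adam) whose loss adds to the reconstruction error a sketch-map
pairwise-distance term: the mean squared difference between
sigmoid-transformed distances in fingerprint space and in map space, with
separate high- and low-dimensional sigmoid parameter sets
$(\sigma_h, a_h, b_h) = (1.1, 6, 6)$ and $(\sigma_l, a_l, b_l) = (1, 2, 6)$.
The sigmoid $s(r) = 1 - (1 + (2^{a/b}-1)(r/\sigma)^a)^{-b/a}$ satisfies
$s(0)=0$ and $s(\sigma)=1/2$ for any $a, b$ and suppresses both very small
and very large distances. Architecture, training length (default 300 Adam
steps, batch 256, learning rate $10^{-3}$, $L_2$ regularization $10^{-5}$)
and batch size are this package's own defaults, chosen so training a
2000-frame ensemble takes seconds; no equivalence with any published
network's training schedule is claimed. All stochastic steps take an
explicit seed and are deterministic given it. **UMAP** is delegated to
umap-learn with a fixed `random_state`.

## Density clustering

Clustering delegates to `sklearn.cluster.HDBSCAN` behind a thin contract:
`min_cluster_size`, `min_samples` and `cluster_selection_method`
("eom"/"leaf") are passed through verbatim and recorded in the result.
Cluster ids are relabeled to contiguous `0..K-1` by decreasing population;
noise keeps −1. A zero-variance embedding (all points identical) is treated
as a single cluster with no noise, since density clustering is degenerate
there. `config.HDBSCAN_PRESETS` ships the parameter blocks used for
full-scale (~300k-frame) analyses — PCA (100, 800, eom), autoencoder map
(100, 1200, leaf), isolated-domain UMAP (1500, 1500, eom) — plus a
`synthetic` preset (100, 25, eom) scaled to the default 2000-frame synthetic
ensembles, since `min_samples` acts as an absolute smoothing count and must
scale with the data set.

## State characterization

Noise frames are excluded from all cluster summaries, consensus graphs and
representative selection; they appear only in whole-landscape colorings.

- **Populations**: member count over total frames; fractions over clusters
  plus noise sum to 1 exactly.
- **Mean fingerprint**: column-wise arithmetic mean over member rows.
- **Consensus graph**: the mean adjacency matrix over cluster members; each
  weight is the contact's occurrence probability in the cluster, and equals
  the cluster mean of the per-frame contact indicator by construction.
  Backbone edges have weight exactly 1. For display, weights are binned into
  [0.25, 0.50) low, [0.50, 0.75) mid, [0.75, 1] high; the half-open-left
  boundary convention is this package's choice, as the printed ranges do not
  specify boundary membership. Weights below 0.25 are not displayed.
- **Difference graph**: elementwise difference of two consensus graphs;
  antisymmetric under swapping the pair; arcs drawn for absolute differences
  above a threshold (default 0.5), colored by sign.
- **Interface score**: the N-terminal domain is split into two sections at a
  chosen residue; cross-domain contacts with the first section count +1,
  with the second −1. Backbone pairs never cross disjoint domains.
- **Radius of gyration**: mass-weighted RMS distance from the center of
  mass, over protein heavy atoms by default (selection configurable).
- **Representatives**: (i) *evenly spaced* — indices
  `round(i·(M−1)/(n−1))` for `i = 0..n−1` over the ordered member list
  (first and last always included; all members if `M < n`; the first member
  for `n = 1`); (ii) *exemplars* — if the clustering backend exposes
  exemplar points they are reduced to `n` by the evenly-spaced rule,
  otherwise the members with the smallest mean distance to their ~15 nearest
  within-cluster neighbors in the embedding (the densest core, top 10 % and
  at least `n`, kept in frame order) stand in; scikit-learn's HDBSCAN does
  not expose exemplars, so the fallback is the default route; (iii)
  *centroid* — the exemplar minimizing summed Euclidean fingerprint distance
  to all other exemplars, ties broken by the lowest frame index.

## Synthetic data

The generator emulates the study conditions the pipeline is meant for: a
two-domain protein with a flexible linker that exchanges between an open
conformation and several closed conformations with distinct domain
interfaces. Each residue is one backbone bead plus one side-chain satellite
(the contact atom), so the minimum-side-chain-distance criterion is
exercised nontrivially. Domains are serpentine bead lattices (0.38 nm
spacing, giving dense intradomain contacts), the linker is a straight
interpolation between the domain anchors, and the two domains are separated
by a surface gap of 3.0 nm in the open state and 0.7 nm in closed states.
Each closed state's planted interface pairs are realized by relocating the
CD partner residue next to its ND partner with a 0.30 nm side-chain
distance, well below the 0.45 nm cutoff. Frames draw a state from the
mixture weights (defaults 0.40 open / 0.35 / 0.25 closed) and add isotropic
Gaussian jitter (default σ = 0.03 nm) to the rigid template — the simplest
noise model that preserves planted contact topology while letting marginal
contacts fluctuate. Default sizes (ND 40, linker 8, CD 35 residues;
2000 frames) keep a full pipeline run to a few seconds on one CPU.

What the generator does *not* emulate: amino-acid chemistry, secondary
structure, realistic kinetics or basin anisotropy, gradual opening/closing
transitions, and force-field energetics. Passing the recovery tests
therefore demonstrates that the pipeline's plumbing, featurization and
clustering are correct and state-discriminating on well-separated contact
topologies — not that any particular real protein's states are recoverable
at a given trajectory length.

## Numerical choices

- Strict `<` at the contact threshold; ties at exactly the cutoff are
  non-contacts.
- BFS distances are exact integers; closeness values are exact ratios
  (verified against rational arithmetic at small N in the tests).
- PCA uses the full SVD solver for reproducibility; component sign is not
  pinned.
- SVG output pins the matplotlib hash salt and strips date metadata so
  identical inputs produce byte-identical files.
- Seeds: every stochastic step takes an explicit integer seed; the pipeline
  logs the resolved configuration including seeds in its manifest.

## Known limitations

- The autoencoder embedder is a reduced-fidelity, CPU-only implementation:
  no periodicity handling, no GPU, fixed simple architecture. For large
  ensembles PCA is the robust default.
- `min_samples`/`min_cluster_size` do not transfer across ensemble sizes;
  the presets document the sizes they were chosen for.
- Exemplar selection approximates dense-core membership via a k-nearest-
  neighbor density when the backend exposes no exemplar points; the two
  routes can differ near cluster boundaries.
- Periodic-image handling supports orthorhombic boxes only and is off by
  default.
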