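"""Synthetic multi-state two-domain bead trajectories with planted RIN states.

The generator emulates the contact behavior of a two-domain protein joined by
a flexible linker: an *open* state with fully separated domains and one or
more *closed* states, each defined by a distinct set of cross-domain residue
pairs forced into side-chain contact. Every residue is modeled as a backbone
bead plus one side-chain satellite atom, so the minimum-side-chain-distance
contact criterion is exercised nontrivially. State geometry templates are
rigid; frames add isotropic Gaussian positional jitter, the simplest noise
model that preserves the planted contact topology at small sigma while
letting marginal contacts fluctuate.

Default sizes (ND 40, linker 8, CD 35 residues) keep full-pipeline runs in
the seconds range. The generator knows nothing of amino-acid chemistry,
secondary structure, or force fields — only contact topology is planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .rin import ContactGraph
from .traj_io import ResidueTopology, TrajectoryEnsemble

_LATTICE_SPACING = 0.38   # nm between consecutive backbone beads
_SATELLITE_OFFSET = 0.10  # nm from backbone bead to side-chain satellite
_PLANT_BACKBONE = 0.50    # nm: moved interface residue's backbone from partner
_PLANT_SIDECHAIN = 0.30   # nm: planted satellite-satellite distance (< cutoff)


@dataclass(frozen=True)
class StateSpec:
    """One planted conformational state.

    ``interface_pairs`` are (ND residue, CD residue) index pairs forced into
    side-chain contact; ``separation`` is the surface-to-surface gap between
    the domains in nm (large for the open state, small for closed ones).
    """

    name: str
    weight: float
    interface_pairs: frozenset = frozenset()
    separation: float = 3.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of a synthetic two-domain ensemble."""

    n_residues_nd: int = 40
    n_linker: int = 8
    n_residues_cd: int = 35
    states: tuple = (
        StateSpec("open", 0.40, frozenset(), 3.0),
        StateSpec("closed_a", 0.35, frozenset({(4, 52), (9, 57)}), 0.7),
        StateSpec("closed_b", 0.25, frozenset({(35, 78), (30, 73)}), 0.7),
    )
    jitter_sigma: float = 0.03
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise GenerationError("jitter_sigma must be non-negative")
        w = sum(s.weight for s in self.states)
        if abs(w - 1.0) > 1e-9:
            raise GenerationError(f"state weights must sum to 1, got {w}")
        nd = range(self.n_residues_nd)
        cd = range(self.n_residues_nd + self.n_linker, self.n_residues)
        for s in self.states:
            for i, j in s.interface_pairs:
                if i not in nd or j not in cd:
                    raise GenerationError(
                        f"state {s.name!r}: interface pair ({i}, {j}) is not "
                        f"(ND residue, CD residue) with ND = 0..{self.n_residues_nd - 1}, "
                        f"CD = {cd.start}..{cd.stop - 1}")

    @property
    def n_residues(self) -> int:
        return self.n_residues_nd + self.n_linker + self.n_residues_cd

    @property
    def nd_range(self) -> tuple[int, int]:
        return (0, self.n_residues_nd - 1)

    @property
    def cd_range(self) -> tuple[int, int]:
        return (self.n_residues_nd + self.n_linker, self.n_residues - 1)


def _snake_lattice(n: int, width: int = 4, height: int = 4) -> np.ndarray:
    """Backbone bead positions on a serpentine path through a cubic lattice.

    Consecutive residues are lattice neighbors, giving a compact, connected
    domain with many intradomain contacts.
    """
    pts = np.empty((n, 3))
    for r in range(n):
        layer, rem = divmod(r, width * height)
        row, col = divmod(rem, width)
        if row % 2 == 1:
            col = width - 1 - col
        if layer % 2 == 1:
            row = height - 1 - row
        pts[r] = (col, row, layer)
    return pts * _LATTICE_SPACING


def _satellite_directions(n: int, seed: int) -> np.ndarray:
    """Deterministic pseudo-random unit vectors, one per residue."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _state_template(spec: SyntheticSpec, state: StateSpec) -> np.ndarray:
    """Rigid coordinate template (A, 3) for one state; atoms alternate
    backbone bead (2r) and satellite (2r + 1) per residue r."""
    n_nd, n_lk, n_cd = spec.n_residues_nd, spec.n_linker, spec.n_residues_cd
    n_res = spec.n_residues

    nd = _snake_lattice(n_nd)
    cd = _snake_lattice(n_cd)
    # place CD beyond ND along x by the requested surface gap
    offset = nd[:, 0].max() - cd[:, 0].min() + state.separation
    cd = cd + np.array([offset, 0.0, 0.0])

    backbone = np.empty((n_res, 3))
    backbone[:n_nd] = nd
    backbone[n_nd + n_lk:] = cd
    # linker: straight interpolation between the domain anchor beads
    start, end = nd[-1], cd[0]
    for t in range(n_lk):
        frac = (t + 1) / (n_lk + 1)
        backbone[n_nd + t] = start + frac * (end - start)

    dirs = _satellite_directions(n_res, seed=spec.seed + 7919)
    coords = np.empty((2 * n_res, 3))
    coords[0::2] = backbone
    coords[1::2] = backbone + _SATELLITE_OFFSET * dirs

    # plant the interface: relocate each CD partner next to its ND residue
    cd_center = cd.mean(axis=0)
    for i, j in sorted(state.interface_pairs):
        u = cd_center - backbone[i]
        u = u / np.linalg.norm(u)
        coords[2 * j] = coords[2 * i] + _PLANT_BACKBONE * u
        coords[2 * j + 1] = coords[2 * i + 1] + _PLANT_SIDECHAIN * u
    return coords


def synthetic_topology(spec: SyntheticSpec) -> ResidueTopology:
    """Residue topology of the bead model: satellite = side-chain contact atom."""
    n = spec.n_residues
    return ResidueTopology(
        n_residues=n,
        residue_labels=tuple(("RES", r + 1, "A") for r in range(n)),
        contact_atoms=tuple((2 * r + 1,) for r in range(n)),
        backbone_pairs=frozenset((r, r + 1) for r in range(n - 1)),
        n_atoms=2 * n,
        masses=tuple([12.0] * 2 * n),
    )


def generate_two_domain_ensemble(spec: SyntheticSpec) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Draw an ensemble of jittered state templates with planted labels.

    Each frame's state is drawn from the state weights; coordinates are the
    state's rigid template plus isotropic Gaussian jitter. Deterministic for
    a fixed ``spec.seed``. Returns the ensemble and the per-frame planted
    state indices (into ``spec.states``).
    """
    topology = synthetic_topology(spec)
    templates = [_state_template(spec, s) for s in spec.states]
    # sanity: planted contacts must be realizable below the jittered cutoff
    for s, tpl in zip(spec.states, templates):
        for i, j in s.interface_pairs:
            d = np.linalg.norm(tpl[2 * i + 1] - tpl[2 * j + 1])
            if d > 0.40:
                raise GenerationError(
                    f"state {s.name!r}: planted pair ({i}, {j}) ended up at "
                    f"{d:.3f} nm, too far for a robust contact")

    rng = np.random.default_rng(spec.seed)
    weights = np.array([s.weight for s in spec.states])
    planted = rng.choice(len(spec.states), size=spec.n_frames, p=weights)
    frames = np.empty((spec.n_frames, topology.n_atoms, 3))
    for f, s in enumerate(planted):
        frames[f] = templates[s] + rng.normal(0.0, spec.jitter_sigma,
                                              size=(topology.n_atoms, 3))
    ensemble = TrajectoryEnsemble(
        frames=frames,
        frame_ids=tuple(("synthetic", f) for f in range(spec.n_frames)),
        topology=topology,
    )
    return ensemble, planted


def generate_random_connected_graph(n: int, p: float, seed: int) -> ContactGraph:
    """Erdos-Renyi graph with a forced spanning path (mimicking the backbone).

    Always connected; p = 0 gives the path graph P_n, p = 1 the complete
    graph K_n.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 nodes, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    np.fill_diagonal(adj, False)
    return ContactGraph(adjacency=adj, cutoff=float("nan"), frame_id=("random", seed))


def write_synthetic_pdb(ensemble: TrajectoryEnsemble, path) -> None:
    """Write the bead ensemble as a multi-model PDB (CA bead + CB satellite)."""
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    carbon = md.element.carbon
    for name, seq, _ in ensemble.topology.residue_labels:
        res = top.add_residue("ALA", chain, resSeq=seq)
        top.add_atom("CA", carbon, res)
        top.add_atom("CB", carbon, res)
    traj = md.Trajectory(xyz=ensemble.frames.astype(np.float32), topology=top)
    traj.save_pdb(str(path))


def write_labels_csv(planted: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("frame,state\n")
        for f, s in enumerate(planted):
            fh.write(f"{f},{int(s)}\n")
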