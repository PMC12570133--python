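"""Reading structures/trajectories and deriving the residue-level contact topology.

All coordinates are handled internally in nanometres (mdtraj's native unit);
user-facing distance cutoffs are accepted in Angstrom and converted once at the
boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import mdtraj as md

from .errors import FormatError, TopologyError

log = logging.getLogger(__name__)

#: standard protein backbone atom names excluded from the side-chain contact set
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA"}


def angstrom_to_nm(value: float) -> float:
    """Convert a length from Angstrom to nanometres."""
    return value * 0.1


@dataclass(frozen=True)
class ResidueTopology:
    """Residue-level view of a structure used for contact computation.

    Parameters
    ----------
    n_residues
        Number of residues N (graph nodes).
    residue_labels
        Ordered ``(name, sequence_number, chain_id)`` per residue, in file order.
    contact_atoms
        Per-residue tuple of atom indices used in the minimum-distance contact
        criterion: side-chain heavy atoms, or the designated fallback for
        residues without any (glycine).
    backbone_pairs
        Frozenset of ``(i, i+1)`` index pairs for residues consecutive in
        sequence within the same chain; these always carry a graph edge.
    n_atoms
        Total atom count of the underlying structure.
    """

    n_residues: int
    residue_labels: tuple[tuple[str, int, str], ...]
    contact_atoms: tuple[tuple[int, ...], ...]
    backbone_pairs: frozenset[tuple[int, int]]
    n_atoms: int
    masses: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise TopologyError(f"need at least 2 residues, got {self.n_residues}")
        if len(self.contact_atoms) != self.n_residues:
            raise TopologyError("contact_atoms length does not match n_residues")
        for i, atoms in enumerate(self.contact_atoms):
            if len(atoms) == 0:
                raise TopologyError(f"residue {i} has an empty contact-atom set")
        for i, j in self.backbone_pairs:
            if j != i + 1:
                raise TopologyError(f"backbone pair ({i},{j}) is not sequence-consecutive")


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """A stack of frames plus the residue topology they live on.

    ``frames`` has shape (F, A, 3) in nm; ``frame_ids`` is an ordered list of
    ``(trajectory_id, frame_index)`` pairs, unique across the ensemble.
    """

    frames: np.ndarray
    frame_ids: tuple[tuple[str, int], ...]
    topology: ResidueTopology

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise FormatError(f"frames must have shape (F, A, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise FormatError("ensemble must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"coordinate atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if len(self.frame_ids) != self.frames.shape[0]:
            raise FormatError("frame_ids length does not match frame count")
        if len(set(self.frame_ids)) != len(self.frame_ids):
            raise FormatError("frame_ids are not unique")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def build_topology(topology: md.Topology, glycine_fallback: str = "ca") -> ResidueTopology:
    """Derive the residue-level contact topology from a parsed structure.

    Contact atoms are side-chain heavy atoms. Residues lacking any (glycine,
    or truncated residues) fall back to the alpha-carbon (``glycine_fallback=
    "ca"``) or to all backbone heavy atoms (``"backbone"``). Backbone pairs
    link residues consecutive in the same chain with consecutive sequence
    numbers; a chain break (new chain id or a jump in numbering) breaks the
    backbone path.
    """
    residues = list(topology.residues)
    if len(residues) < 2:
        raise TopologyError(f"need at least 2 residues, got {len(residues)}")

    labels: list[tuple[str, int, str]] = []
    contact_atoms: list[tuple[int, ...]] = []
    masses = np.zeros(topology.n_atoms)
    for res in residues:
        atoms = list(res.atoms)
        if not atoms:
            raise TopologyError(f"residue {res} has zero atoms")
        for a in atoms:
            masses[a.index] = a.element.mass if a.element is not None else 0.0
        chain_id = _chain_label(res)
        labels.append((res.name, res.resSeq, chain_id))
        sidechain = [
            a.index for a in atoms
            if a.element is not None and a.element.symbol != "H" and a.name not in _BACKBONE_NAMES
        ]
        if sidechain:
            contact_atoms.append(tuple(sidechain))
        else:
            if glycine_fallback == "ca":
                fallback = [a.index for a in atoms if a.name == "CA"]
            elif glycine_fallback == "backbone":
                fallback = [
                    a.index for a in atoms
                    if a.element is not None and a.element.symbol != "H"
                ]
            else:
                raise ValueError(f"unknown glycine_fallback {glycine_fallback!r}")
            if not fallback:
                # last resort: any heavy atom at all keeps the residue usable
                fallback = [a.index for a in atoms if a.element is None or a.element.symbol != "H"]
            if not fallback:
                raise TopologyError(f"residue {res} has no heavy atom usable for contacts")
            log.warning("residue %s has no side-chain heavy atoms; using fallback %r",
                        res, glycine_fallback)
            contact_atoms.append(tuple(fallback))

    backbone_pairs = set()
    for i in range(len(residues) - 1):
        a, b = residues[i], residues[i + 1]
        same_chain = _chain_label(a) == _chain_label(b)
        consecutive = b.resSeq == a.resSeq + 1
        if same_chain and consecutive:
            backbone_pairs.add((i, i + 1))

    return ResidueTopology(
        n_residues=len(residues),
        residue_labels=tuple(labels),
        contact_atoms=tuple(contact_atoms),
        backbone_pairs=frozenset(backbone_pairs),
        n_atoms=topology.n_atoms,
        masses=tuple(masses),
    )


def _chain_label(res) -> str:
    cid = res.chain.chain_id
    return cid if cid else str(res.chain.index)


def load_ensemble(
    topology_file: str | os.PathLike,
    coordinate_files: Sequence[str | os.PathLike],
    glycine_fallback: str = "ca",
) -> TrajectoryEnsemble:
    """Load one or more coordinate files against a shared topology.

    Frames are concatenated in file order; ``frame_ids`` are
    ``(basename, frame_index)`` so provenance survives concatenation.
    Supported: PDB/GRO topology; XTC, DCD, or multi-model PDB coordinates.
    """
    topology_file = os.fspath(topology_file)
    if not os.path.exists(topology_file):
        raise FormatError(f"topology file not found: {topology_file}")
    try:
        ref = md.load_topology(topology_file)
    except Exception as exc:  # noqa: BLE001 - re-raise as our I/O error
        raise FormatError(f"could not read topology file {topology_file}: {exc}") from exc

    residue_topology = build_topology(ref, glycine_fallback=glycine_fallback)

    blocks: list[np.ndarray] = []
    frame_ids: list[tuple[str, int]] = []
    for path in coordinate_files:
        path = os.fspath(path)
        if not os.path.exists(path):
            raise FormatError(f"coordinate file not found: {path}")
        try:
            if path.endswith(".pdb"):
                traj = md.load(path)
            else:
                traj = md.load(path, top=ref)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not read coordinate file {path}: {exc}") from exc
        if traj.n_atoms != ref.n_atoms:
            raise FormatError(
                f"atom count mismatch: topology has {ref.n_atoms} atoms but "
                f"{path} has {traj.n_atoms}"
            )
        blocks.append(np.asarray(traj.xyz, dtype=np.float64))
        base = os.path.basename(path)
        frame_ids.extend((base, i) for i in range(traj.n_frames))

    if not blocks:
        raise FormatError("no coordinate files given")
    frames = np.concatenate(blocks, axis=0)
    log.info("loaded %d frames, %d atoms, %d residues from %d file(s)",
             frames.shape[0], frames.shape[1], residue_topology.n_residues, len(blocks))
    return TrajectoryEnsemble(frames=frames, frame_ids=tuple(frame_ids),
                              topology=residue_topology)
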