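"""Shared fixtures: small synthetic ensembles, hand-built graphs and peptides."""

from __future__ import annotations

import numpy as np
import pytest

from rin_states import (
    ContactGraph,
    SyntheticSpec,
    build_rins,
    fingerprint_matrix,
    generate_two_domain_ensemble,
    normalize_fingerprints,
)


def path_graph(n: int) -> ContactGraph:
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return ContactGraph(adjacency=adj, cutoff=0.45)


def complete_graph(n: int) -> ContactGraph:
    adj = np.ones((n, n), dtype=bool)
    np.fill_diagonal(adj, False)
    return ContactGraph(adjacency=adj, cutoff=0.45)


def star_graph(n_leaves: int) -> ContactGraph:
    n = n_leaves + 1
    adj = np.zeros((n, n), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    return ContactGraph(adjacency=adj, cutoff=0.45)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Fast 3-state spec (open + two closed interfaces) for unit tests."""
    return SyntheticSpec(n_frames=300, seed=11)


@pytest.fixture(scope="session")
def small_ensemble(small_spec):
    return generate_two_domain_ensemble(small_spec)


@pytest.fixture(scope="session")
def small_graphs(small_ensemble):
    ensemble, _ = small_ensemble
    return build_rins(ensemble)


@pytest.fixture(scope="session")
def small_fingerprints(small_ensemble, small_graphs):
    ensemble, _ = small_ensemble
    return normalize_fingerprints(fingerprint_matrix(ensemble, small_graphs))


@pytest.fixture()
def tripeptide_topology():
    """ALA-GLY-ALA as an mdtraj topology (heavy atoms only)."""
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    elems = {"N": md.element.nitrogen, "CA": md.element.carbon,
             "C": md.element.carbon, "O": md.element.oxygen,
             "CB": md.element.carbon}
    for i, name in enumerate(["ALA", "GLY", "ALA"]):
        res = top.add_residue(name, chain, resSeq=i + 1)
        atoms = ["N", "CA", "C", "O"] + (["CB"] if name == "ALA" else [])
        for a in atoms:
            top.add_atom(a, elems[a], res)
    return top
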