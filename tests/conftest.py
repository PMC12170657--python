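"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive — matrix-powering for shortest-path
distances and exhaustive simple-path enumeration for detour distances — so
they share no code path with the implementations they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from tcaqspr import (
    HydrogenMode,
    MolecularGraph,
    compute_index_table,
    load_dataset,
    load_properties,
    load_reference_indices,
)


def graph_from_edges(n: int, edges, mode=HydrogenMode.HEAVY_ONLY) -> MolecularGraph:
    return MolecularGraph(
        n=n,
        edges=frozenset(tuple(sorted(e)) for e in edges),
        mode=mode,
        vertex_labels=tuple("C" * n),
    )


def path_graph(n: int) -> MolecularGraph:
    return graph_from_edges(n, [(i, i + 1) for i in range(n - 1)])


def cycle_graph(n: int) -> MolecularGraph:
    return graph_from_edges(n, [(i, (i + 1) % n) for i in range(n)])


def power_distance_oracle(g: MolecularGraph) -> np.ndarray:
    """Shortest-path distances via adjacency-matrix powering (reachability)."""
    A = np.zeros((g.n, g.n), dtype=np.int64)
    for a, b in g.edges:
        A[a, b] = A[b, a] = 1
    d = np.full((g.n, g.n), -1, dtype=np.int64)
    np.fill_diagonal(d, 0)
    reach = np.eye(g.n, dtype=np.int64)
    for k in range(1, g.n):
        reach = reach @ A
        newly = (reach > 0) & (d < 0)
        d[newly] = k
    if (d < 0).any():
        raise ValueError("disconnected graph")
    return d


def brute_detour_oracle(g: MolecularGraph) -> np.ndarray:
    """Detour distances via exhaustive all-simple-paths enumeration."""
    G = g.to_networkx()
    D = np.zeros((g.n, g.n), dtype=np.int64)
    for a, b in itertools.combinations(range(g.n), 2):
        longest = max(len(p) - 1 for p in nx.all_simple_paths(G, a, b))
        D[a, b] = D[b, a] = longest
    return D


@pytest.fixture(scope="session")
def records():
    return load_dataset()


@pytest.fixture(scope="session")
def by_abbr(records):
    return {r.abbreviation: r for r in records}


@pytest.fixture(scope="session")
def props():
    return load_properties()


@pytest.fixture(scope="session")
def heavy_ref():
    return load_reference_indices(HydrogenMode.HEAVY_ONLY)


@pytest.fixture(scope="session")
def allh_ref():
    return load_reference_indices(HydrogenMode.ALL_H)


@pytest.fixture(scope="session")
def computed_heavy(records):
    return compute_index_table([r.molecule for r in records], HydrogenMode.HEAVY_ONLY)


@pytest.fixture(scope="session")
def computed_allh(records):
    return compute_index_table([r.molecule for r in records], HydrogenMode.ALL_H)
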