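"""Molecular graphs and their distance/detour matrices.

A molecule is reduced to a simple, undirected, connected graph in one of two
hydrogen representations:

* ``HEAVY_ONLY`` — the H-suppressed skeleton: vertices are non-hydrogen atoms,
  one edge per covalent bond between heavy atoms.  Bond orders, aromaticity,
  charges and stereochemistry are discarded; a double bond and a single bond
  contribute the same single edge.
* ``ALL_H`` — every hydrogen becomes an explicit pendant (degree-1) vertex
  attached to its heavy atom.

Two all-pairs matrices are defined on such a graph: the shortest-path distance
matrix ``d`` (unit edge weights, BFS) and the detour matrix ``D`` whose entry
``D[a, b]`` is the length of the *longest simple path* between ``a`` and
``b``.  Longest simple path is NP-hard in general, but molecular graphs have
tiny biconnected blocks (individual rings or small fused ring systems), so the
detour matrix is computed exactly by composing per-block longest paths along
the block–cut tree; each block is searched exhaustively by depth-first
enumeration under an explicit expansion budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "HydrogenMode",
    "Molecule",
    "MolecularGraph",
    "PairMatrices",
    "SmilesParseError",
    "StructureError",
    "DetourBudgetError",
    "parse_smiles",
    "build_graph",
    "shortest_path_matrix",
    "detour_matrix",
    "pair_matrices",
]

#: Default cap on depth-first path expansions per biconnected block.  Blocks in
#: drug-like molecules are single rings or small fused systems and stay far
#: below this; the cap exists so a pathological dense input fails loudly
#: instead of hanging.
DEFAULT_DETOUR_BUDGET = 10_000_000


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class StructureError(ValueError):
    """Raised for structurally invalid input (e.g. a disconnected graph)."""


class DetourBudgetError(RuntimeError):
    """Raised when per-block path enumeration exceeds its expansion budget."""


class HydrogenMode(str, Enum):
    """Hydrogen representation of the molecular graph.

    ``HEAVY_ONLY`` is the H-suppressed skeleton; ``ALL_H`` attaches every
    hydrogen as an explicit pendant vertex.
    """

    HEAVY_ONLY = "heavy"
    ALL_H = "all-h"


@dataclass(frozen=True)
class Molecule:
    """Parsed chemical structure for one compound.

    ``atoms`` holds ``(element symbol, implicit hydrogen count)`` per heavy
    atom, in parse order; ``bonds`` holds unordered heavy-atom index pairs.
    """

    name: str
    abbreviation: str
    smiles: str
    atoms: tuple[tuple[str, int], ...]
    bonds: frozenset[tuple[int, int]]

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    @property
    def n_hydrogens(self) -> int:
        return sum(h for _, h in self.atoms)


@dataclass(frozen=True)
class MolecularGraph:
    """Simple undirected connected graph under a chosen hydrogen mode.

    Vertices are ``0 .. n-1``; ``vertex_labels`` carries element symbols for
    inspection only and plays no role in any computation.
    """

    n: int
    edges: frozenset[tuple[int, int]]
    mode: HydrogenMode
    vertex_labels: tuple[str, ...] = field(default=())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class PairMatrices:
    """All-pairs shortest-path (``d``) and detour (``D``) matrices."""

    d: np.ndarray
    D: np.ndarray


def _normalize_edge(a: int, b: int) -> tuple[int, int]:
    if a == b:
        raise StructureError(f"self-loop on vertex {a}")
    return (a, b) if a < b else (b, a)


def parse_smiles(smiles: str, name: str = "", abbreviation: str = "") -> Molecule:
    """Parse a SMILES string into heavy-atom connectivity plus H counts.

    Parsing and valence completion are delegated to RDKit; only the simple
    underlying connectivity and per-atom total hydrogen counts are retained.

    Raises
    ------
    SmilesParseError
        If the SMILES is not syntactically valid.
    StructureError
        If the heavy-atom graph is disconnected (multi-component input).
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = name or smiles
        raise SmilesParseError(f"unparsable SMILES for {label!r}: {smiles!r}")
    atoms = tuple((a.GetSymbol(), a.GetTotalNumHs()) for a in mol.GetAtoms())
    bonds = frozenset(
        _normalize_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    )
    if len(Chem.GetMolFrags(mol)) != 1:
        label = name or smiles
        raise StructureError(f"disconnected heavy-atom graph for {label!r}")
    return Molecule(
        name=name, abbreviation=abbreviation, smiles=smiles, atoms=atoms, bonds=bonds
    )


def build_graph(mol: Molecule, mode: HydrogenMode) -> MolecularGraph:
    """Build the simple graph of ``mol`` under ``mode``.

    Under ``ALL_H`` each implicit hydrogen of heavy atom ``i`` becomes a new
    pendant vertex adjacent only to ``i``; hydrogens are appended after all
    heavy atoms, in heavy-atom order.
    """
    mode = HydrogenMode(mode)
    labels = [sym for sym, _ in mol.atoms]
    edges = set(mol.bonds)
    n = mol.n_heavy
    if mode is HydrogenMode.ALL_H:
        for i, (_, h) in enumerate(mol.atoms):
            for _ in range(h):
                edges.add((i, n))
                labels.append("H")
                n += 1
    return MolecularGraph(
        n=n, edges=frozenset(edges), mode=mode, vertex_labels=tuple(labels)
    )


def shortest_path_matrix(g: MolecularGraph) -> np.ndarray:
    """Unit-weight all-pairs shortest-path matrix (BFS), as integers.

    Raises :class:`StructureError` on a disconnected graph — infinite
    distances are never emitted.
    """
    if g.n == 0:
        raise StructureError("empty graph")
    rows, cols = [], []
    for a, b in g.edges:
        rows += [a, b]
        cols += [b, a]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(g.n, g.n))
    d = _csgraph_shortest_path(adj, method="D", unweighted=True)
    if np.isinf(d).any():
        raise StructureError("graph is disconnected")
    return d.astype(np.int64)


# --------------------------------------------------------------------------
# Detour matrix via block–cut-tree composition
# --------------------------------------------------------------------------


class _BlockSearcher:
    """Exhaustive longest-simple-path search inside one biconnected block.

    One DFS sweep from a source vertex records the longest simple path to
    every other vertex of the block, so results are cached per source.  The
    expansion counter is shared across sweeps of the same block and enforces
    the per-block budget.
    """

    def __init__(self, block: nx.Graph, budget: int) -> None:
        self.adj = {v: sorted(block[v]) for v in block}
        self.budget = budget
        self.expansions = 0
        self._cache: dict[int, dict[int, int]] = {}

    def longest_from(self, s: int) -> dict[int, int]:
        if s in self._cache:
            return self._cache[s]
        best = {v: 0 for v in self.adj}
        on_path = {s}
        stack: list[tuple[int, int, "object"]] = [(s, 0, iter(self.adj[s]))]
        while stack:
            u, length, it = stack[-1]
            advanced = False
            for w in it:
                if w in on_path:
                    continue
                self.expansions += 1
                if self.expansions > self.budget:
                    raise DetourBudgetError(
                        f"detour search exceeded {self.budget} expansions in a "
                        f"{len(self.adj)}-vertex block"
                    )
                if length + 1 > best[w]:
                    best[w] = length + 1
                on_path.add(w)
                stack.append((w, length + 1, iter(self.adj[w])))
                advanced = True
                break
            if not advanced:
                stack.pop()
                on_path.discard(u)
        self._cache[s] = best
        return best

    def detour(self, s: int, t: int) -> int:
        return self.longest_from(s)[t]


def detour_matrix(
    g: MolecularGraph, budget: int = DEFAULT_DETOUR_BUDGET
) -> np.ndarray:
    """Exact all-pairs detour (longest simple path) matrix.

    The graph is decomposed into biconnected blocks.  Any simple path between
    two vertices traverses the unique sequence of blocks joining them in the
    block–cut tree, entering and leaving each intermediate block through its
    cut vertices, so the detour distance is the sum of within-block detour
    segments along that sequence.  Within a block, longest paths are found by
    exhaustive depth-first enumeration (budgeted; see
    :data:`DEFAULT_DETOUR_BUDGET`).

    Agrees with naive all-simple-paths enumeration on every connected simple
    graph; raises :class:`DetourBudgetError` rather than approximating if a
    block is too dense to enumerate.
    """
    G = g.to_networkx()
    n = g.n
    if n == 0:
        raise StructureError("empty graph")
    if not nx.is_connected(G):
        raise StructureError("graph is disconnected")

    blocks = [tuple(sorted(b)) for b in nx.biconnected_components(G)]
    cuts = set(nx.articulation_points(G))
    tree = nx.Graph()
    home: dict[int, tuple[str, int]] = {}
    for bi, block in enumerate(blocks):
        tree.add_node(("B", bi))
        for v in block:
            if v in cuts:
                tree.add_edge(("B", bi), ("C", v))
            else:
                home[v] = ("B", bi)
    for v in cuts:
        home[v] = ("C", v)

    searchers = [_BlockSearcher(G.subgraph(b), budget) for b in blocks]
    D = np.zeros((n, n), dtype=np.int64)
    # Tree paths between all homes, computed once per home pair.
    tree_paths: dict[tuple, list] = {}
    for a, b in itertools.combinations(range(n), 2):
        ha, hb = home[a], home[b]
        if ha == hb:  # both interior to the same block
            dist = searchers[ha[1]].detour(a, b)
        else:
            key = (ha, hb)
            if key not in tree_paths:
                tree_paths[key] = nx.shortest_path(tree, ha, hb)
            path = tree_paths[key]
            dist = 0
            cur = a
            for pos, node in enumerate(path):
                if node[0] != "B":
                    continue
                # leave this block through the next cut vertex, or arrive at b
                target = path[pos + 1][1] if pos + 1 < len(path) else b
                if target != cur:
                    dist += searchers[node[1]].detour(cur, target)
                    cur = target
        D[a, b] = D[b, a] = dist
    return D


def pair_matrices(g: MolecularGraph, budget: int = DEFAULT_DETOUR_BUDGET) -> PairMatrices:
    """Convenience bundle of both all-pairs matrices for one graph."""
    return PairMatrices(d=shortest_path_matrix(g), D=detour_matrix(g, budget=budget))
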