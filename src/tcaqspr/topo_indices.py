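"""Distance- and detour-based topological indices.

Five classical indices are computed from the all-pairs matrices of a
molecular graph ``G`` with vertex pairs ``a < b``:

* Wiener            ``W(G)  = Σ d(a, b)``
* hyper-Wiener      ``WW(G) = Σ (d(a, b) + d(a, b)²) / 2``
* Harary            ``H(G)  = Σ 1 / d(a, b)``
* detour            ``D(G)  = Σ D(a, b)``
* detour-Harary     ``DH(G) = Σ 1 / D(a, b)``

where ``d`` is the shortest-path distance and ``D`` the detour (longest
simple path) distance.  On trees the two matrices coincide, so ``D = W`` and
``DH = H`` there.  All arithmetic is exact / full precision; rounding happens
only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .molgraph import (
    HydrogenMode,
    Molecule,
    build_graph,
    pair_matrices,
)

__all__ = [
    "INDEX_NAMES",
    "IndexVector",
    "wiener",
    "hyper_wiener",
    "harary",
    "detour_index",
    "detour_harary",
    "compute_index_vector",
    "compute_index_table",
]

#: Column order used throughout (tables, CSV output).
INDEX_NAMES: tuple[str, ...] = ("W", "WW", "H", "D", "DH")


@dataclass(frozen=True)
class IndexVector:
    """The five topological index values for one graph."""

    W: float
    WW: float
    H: float
    D: float
    DH: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.W, self.WW, self.H, self.D, self.DH)


def _upper(mat: np.ndarray) -> np.ndarray:
    """Validate a pair matrix and return its strict upper-triangle entries."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("pair matrix must be square")
    if np.any(np.diag(mat) != 0):
        raise ValueError("pair matrix must have a zero diagonal")
    if not np.array_equal(mat, mat.T):
        raise ValueError("pair matrix must be symmetric")
    vals = mat[np.triu_indices(mat.shape[0], k=1)]
    if vals.size and vals.min() < 1:
        raise ValueError("off-diagonal entries must be >= 1")
    return vals.astype(float)


def wiener(d: np.ndarray) -> float:
    """Sum of shortest-path distances over unordered vertex pairs."""
    return float(_upper(d).sum())


def hyper_wiener(d: np.ndarray) -> float:
    """Half-sum of ``d + d²`` over unordered vertex pairs."""
    v = _upper(d)
    return float(((v + v**2) / 2.0).sum())


def harary(d: np.ndarray) -> float:
    """Sum of reciprocal shortest-path distances over unordered pairs."""
    return float((1.0 / _upper(d)).sum())


def detour_index(D: np.ndarray) -> float:
    """Sum of detour distances over unordered vertex pairs."""
    return float(_upper(D).sum())


def detour_harary(D: np.ndarray) -> float:
    """Sum of reciprocal detour distances over unordered pairs."""
    return float((1.0 / _upper(D)).sum())


def compute_index_vector(d: np.ndarray, D: np.ndarray) -> IndexVector:
    """All five indices from a shortest-path and a detour matrix."""
    return IndexVector(
        W=wiener(d),
        WW=hyper_wiener(d),
        H=harary(d),
        D=detour_index(D),
        DH=detour_harary(D),
    )


def compute_index_table(
    drugs: Iterable[Molecule], mode: HydrogenMode | str
) -> pd.DataFrame:
    """Index table (rows: drugs, columns ``W, WW, H, D, DH``) for one mode.

    Rows are keyed by the molecule's abbreviation when present, otherwise by
    its name.  Deterministic: same input order, same table.
    """
    mode = HydrogenMode(mode)
    rows: dict[str, Sequence[float]] = {}
    for mol in drugs:
        g = build_graph(mol, mode)
        pm = pair_matrices(g)
        rows[mol.abbreviation or mol.name] = compute_index_vector(pm.d, pm.D).as_tuple()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(INDEX_NAMES))


def round_for_report(table: pd.DataFrame, decimals: int = 4) -> pd.DataFrame:
    """Rounded copy for serialization; internal arithmetic stays exact."""
    return table.round(decimals)
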