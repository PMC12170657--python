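"""Synthetic molecule-like graphs and property vectors with known structure.

The generator mirrors the two ingredients the pipeline consumes:

* small connected simple graphs with a low cyclomatic number (random spanning
  tree plus a few chord edges), optionally augmented with degree-1 pendant
  vertices that play the role of explicit hydrogens;
* property vectors generated from a known law — linear ``a + b·t`` or a
  monotone nonlinear exponential ramp — plus homoscedastic Gaussian noise.

Default graph sizes mirror the study regime (20–30 core vertices); oracle
tests use much smaller instances where exhaustive path enumeration is cheap.
Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import HydrogenMode, MolecularGraph

__all__ = [
    "SyntheticGraphConfig",
    "SyntheticPropertyConfig",
    "random_molgraph",
    "synth_properties",
]


@dataclass(frozen=True)
class SyntheticGraphConfig:
    """Ranges (inclusive) for the random graph generator."""

    n_vertices: tuple[int, int] = (20, 30)
    cyclomatic: tuple[int, int] = (0, 4)
    pendant_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_vertices
        if lo < 2 or hi < lo:
            raise ValueError("n_vertices range must satisfy 2 <= lo <= hi")
        clo, chi = self.cyclomatic
        if clo < 0 or chi < clo:
            raise ValueError("cyclomatic range must satisfy 0 <= lo <= hi")
        if not 0 <= self.pendant_prob <= 1:
            raise ValueError("pendant_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticPropertyConfig:
    """Generating law for a synthetic property column.

    ``linear``: ``a + b * t``.  ``nonlinear``: ``a + b * expm1(rate * z)``
    with ``z`` the min-max normalisation of ``t`` — a monotone exponential
    ramp.  With ``noise_sd = 0`` the law is exactly recoverable.
    """

    law: str = "linear"
    intercept: float = 0.0
    slope: float = 1.0
    ramp_rate: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.law not in ("linear", "nonlinear"):
            raise ValueError("law must be 'linear' or 'nonlinear'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def random_molgraph(cfg: SyntheticGraphConfig) -> MolecularGraph:
    """Connected simple graph: random spanning tree plus chord edges.

    A random recursive tree on ``n`` core vertices guarantees connectivity;
    a cyclomatic number drawn from the requested range (clipped to the number
    of available non-edges) is realised by adding that many distinct chords.
    With ``pendant_prob > 0`` each core vertex independently gains one
    pendant vertex, labelled ``H``; the result is then tagged ``ALL_H``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(rng.integers(cfg.n_vertices[0], cfg.n_vertices[1] + 1))
    edges = {(int(rng.integers(0, v)), v) for v in range(1, n)}
    max_extra = n * (n - 1) // 2 - (n - 1)
    c_lo = min(cfg.cyclomatic[0], max_extra)
    c_hi = min(cfg.cyclomatic[1], max_extra)
    c = int(rng.integers(c_lo, c_hi + 1))
    non_edges = [
        (a, b)
        for a in range(n)
        for b in range(a + 1, n)
        if (a, b) not in edges
    ]
    if c > 0:
        chosen = rng.choice(len(non_edges), size=c, replace=False)
        edges.update(non_edges[i] for i in chosen)
    labels = ["C"] * n
    mode = HydrogenMode.HEAVY_ONLY
    if cfg.pendant_prob > 0:
        mode = HydrogenMode.ALL_H
        k = n
        for v in range(n):
            if rng.random() < cfg.pendant_prob:
                edges.add((v, k))
                labels.append("H")
                k += 1
        n = k
    return MolecularGraph(
        n=n, edges=frozenset(edges), mode=mode, vertex_labels=tuple(labels)
    )


def synth_properties(
    index_values: np.ndarray, cfg: SyntheticPropertyConfig
) -> np.ndarray:
    """Property column = law(index) + Gaussian noise, seeded."""
    t = np.asarray(index_values, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("index_values is empty")
    if cfg.law == "linear":
        y = cfg.intercept + cfg.slope * t
    else:
        span = np.ptp(t)
        z = (t - t.min()) / span if span > 0 else np.zeros_like(t)
        y = cfg.intercept + cfg.slope * np.expm1(cfg.ramp_rate * z)
    if cfg.noise_sd > 0:
        y = y + np.random.default_rng(cfg.seed).normal(0.0, cfg.noise_sd, t.size)
    return y
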