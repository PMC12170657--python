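# Methods

## Molecular graphs and hydrogen modes

Structures enter as SMILES; parsing and valence completion are delegated to
RDKit, after which only the simple underlying connectivity is kept. Bond
orders, aromaticity, formal charges and stereochemistry are discarded
deliberately: all five indices are functions of graph distances alone, and
keeping a multigraph or weighted edges would change none of them while
complicating the invariants. Two representations are built per molecule:

* `HEAVY_ONLY` — the H-suppressed skeleton (heavy atoms, one edge per bond);
* `ALL_H` — each implicit hydrogen appended as a pendant vertex on its heavy
  atom, so `n(ALL_H) = n(HEAVY_ONLY) + #H` and every hydrogen has degree 1.

The 15-drug fixture is locked by a molecular-formula cross-check at load
time: the heavy-element counts and total hydrogen count implied by each
SMILES must equal the declared formula, otherwise loading fails naming the
drug. Since two of the headline consistency results are graph
isomorphisms (amitriptyline/imipramine H-suppressed; lorazepam/oxazepam
all-hydrogen, where chlorine substitutes a ring hydrogen), a wrong structure
cannot slip through silently without also breaking those tests.

## Distance and detour matrices

Shortest-path distances are unit-weight BFS distances
(`scipy.sparse.csgraph`), returned as exact integers; a disconnected graph
raises rather than emitting infinities.

The detour distance `D(a,b)` is the length of the longest *simple* path
from `a` to `b` — NP-hard on arbitrary graphs, but tractable here because
molecular graphs have a tree-like block structure. The implementation:

1. decompose the graph into biconnected blocks and cut vertices
   (NetworkX), and build the block–cut tree;
2. for a vertex pair, walk the unique path of blocks joining them; any
   simple path must pass through the same cut-vertex sequence, so the
   detour distance is the sum of per-block detour segments between
   consecutive attachment vertices;
3. inside a block, longest paths are found by exhaustive depth-first
   enumeration. One DFS sweep from a source records the longest simple
   path to every target in the block and is cached per source.

Enumeration carries a per-block expansion budget (default 10⁷). Exceeding
it raises `DetourBudgetError`; the code never falls back to an
approximation. Drug-sized inputs are far below the budget: individual
blocks in this dataset are single rings or one fused tricyclic system
(≤ ~15 vertices), and both matrices for all 15 drugs in both modes compute
in ~0.3 s total. Correctness is established against an independent
exhaustive all-simple-paths oracle on 200 random connected graphs (n ≤ 12,
cyclomatic number ≤ 3) plus tree and cycle closed forms.

## Indices

`W`, `WW`, `H` are sums over the strict upper triangle of the distance
matrix; `D` (detour index) and `DH` (detour-Harary) the same over the
detour matrix. Internal arithmetic is full double precision; rounding to 4
decimal places happens only at serialization. On trees the two matrices
coincide, so `D = W` and `DH = H` there — a property test. Because detour
distances dominate shortest-path distances, `D ≥ W` and `DH ≤ H` always.

## Reference tables and known discrepancies

The fixture carries the published per-mode index tables verbatim, with a
per-cell `suspect` annotation. The all-hydrogen table is reproduced
cell-for-cell for all 15 drugs. The H-suppressed table is not fully
reproducible, and the inconsistencies are provable from the publication's
own all-hydrogen table: the all-hydrogen graph fixes the skeleton, and the
skeleton fixes the H-suppressed indices. Specifically:

* **Desipramine, nortriptyline, protriptyline** — the printed rows duplicate
  the amitriptyline/imipramine row, which belongs to a 21-vertex graph;
  these three skeletons have 20 vertices and give
  (759, 2282, 68.0484, 2328, 22.5787), identical across the three because
  their skeletons are isomorphic. The printed rows *are* obtained if the
  single amine N–H hydrogen is kept as a 21st vertex, which makes the graph
  isomorphic to amitriptyline's skeleton — the likely origin of the
  duplication.
* **Fluoxetine** — the printed row matches the skeleton plus its N–H
  hydrogen (23 vertices), not the 22-vertex skeleton.
* **Amitriptyline, imipramine** — the printed Harary cell (70.7087)
  disagrees with the value implied by the same row's own W/WW/D/DH
  (72.7087, off by exactly 2); only that cell is flagged.
* **Amoxapine, desvenlafaxine, lorazepam, oxazepam** — the printed rows
  match neither the skeleton, nor the skeleton with polar hydrogens, nor
  plausible analogue structures tested; they are flagged wholesale.

The pipeline computes and reports its own values and emits a cell-level
discrepancy report (`discrepancy_report.csv`); it never forces agreement
with a flagged cell. The regression stages consume the *published* tables
by default — including the flagged rows, exactly as the original analysis
used them — because the printed correlation and LR results are only
reproducible from those tables; `--source computed` switches to the
recomputed ones.

## Correlation and linear regression

Pearson coefficients are computed per (index, property) cell on the 15
paired observations; a constant column raises an error rather than being
zeroed. The linear model `u = v + w·t` is fitted by OLS **on all 15
observations with no train/test split**: the published LR R² values equal
the squared published correlations (0.8180² = 0.6692, 0.9250² = 0.8557),
which holds only for full-data fits. RMSE uses denominator `n`, not
`n − 2`. The identity R² = r² is asserted to 1e-12 for every cell.

## SVR protocol

ε-insensitive SVR with the RBF kernel `K(x, y) = exp(−α‖x−y‖²)`; the dual
optimisation is scikit-learn's `SVR`, while this package fixes the
protocol: seeded 80/20 split, 40-point grid (C ∈ {10, 50, 100, 500},
ε ∈ {0.1, 0.2, 0.3, 0.4, 0.5}, γ ∈ {scale, auto} with the conventional
definitions scale = 1/(n_features·var x), auto = 1/n_features), scored by
mean R² over shuffled 5-fold CV on the training split, winner refit on the
whole training split and evaluated on the held-out 20 % (R², RMSE with
denominator n_test). Grid order is deterministic (C ascending, ε ascending,
scale before auto) and only a strictly better CV score displaces the
incumbent, so ties resolve toward the less complex model. A fold whose
validation target is constant scores −∞ instead of an undefined R².

Design choices where the protocol was genuinely open: features are
standardized inside the CV pipeline (off-switch provided and recorded in
the result); the target is left on its raw scale, so the ε grid is in
property units, matching a plain scikit-learn workflow; the default seed
is 42 and is threaded through split and fold shuffling, making every run
reproducible end-to-end — the `reproduce` bundle is byte-identical across
reruns with equal seeds.

The original study's exact SVR numbers depend on a split membership and
seed that are not recoverable, so they are treated as qualitative
references. What is asserted instead: tuned parameters always lie in the
printed grid; on synthetic monotone-nonlinear data SVR's test R² beats
LR's on the same split for a majority of 20 seeded trials; noiseless
linear data yields test R² ≥ 0.99; fixed seeds give byte-identical
reports.

## Synthetic data

`random_molgraph` draws a random recursive spanning tree (connected by
construction) and adds chord edges to reach a cyclomatic number drawn from
the requested range, optionally attaching degree-1 pendants to emulate
explicit hydrogens. Defaults mirror the study regime (20–30 core
vertices, cyclomatic 0–4); oracle tests use n ≤ 12 where exhaustive path
enumeration is cheap. `synth_properties` generates `a + b·t` or a monotone
exponential ramp `a + b·expm1(rate·z)` (z the min-max normalised index),
plus homoscedastic Gaussian noise — the implicit noise model under which
R²/RMSE evaluation is natural. Identical configs and seeds give identical
outputs.

What the generator does *not* emulate: chemical valence rules, realistic
ring-size distributions, or correlated multi-property structure. Passing
tests therefore certify the graph algorithms, the index arithmetic, and
the statistical protocol — not chemical realism of the generator, which
the real 15-drug fixture covers.

## Numerical and reporting conventions

Distances are exact integers; indices are exact up to float summation
order (isomorphic graphs can differ at ~1e-12, which is why identity
checks between isomorphic drugs use a 1e-9 tolerance). CSV output rounds
to 4 decimal places; comparisons against published 4-d.p. values use an
absolute tolerance of 5e-5 (half a unit in the last printed place). Best
models per property are chosen by highest R² (test R² for SVR) with a
lexicographic index-name tie-break. Problem sizes throughout are the
study's own: 15 drugs, graphs of 20–28 heavy atoms (31–71 vertices with
hydrogens), 60 SVR tunes per full run.
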