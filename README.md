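# tcaqspr

Quantitative structure–property relationship (QSPR) analysis of fifteen
tricyclic antidepressant (TCA) drugs built on **distance- and detour-based
topological indices**, with explicit attention to how the hydrogen
representation of the molecular graph changes the answer.

A molecule is reduced to a simple undirected graph — vertices are atoms,
one edge per covalent bond, bond orders ignored — in one of two modes:

* **H-suppressed** (`heavy`): non-hydrogen atoms only;
* **all-hydrogen** (`all-h`): every hydrogen attached as an explicit
  degree-1 pendant vertex.

On each graph five indices are computed from the all-pairs shortest-path
distance `d(a,b)` and detour (longest simple path) distance `D(a,b)`:

| index | definition |
|---|---|
| Wiener `W` | Σ<sub>a&lt;b</sub> d(a,b) |
| hyper-Wiener `WW` | Σ<sub>a&lt;b</sub> (d(a,b) + d(a,b)²)/2 |
| Harary `H` | Σ<sub>a&lt;b</sub> 1/d(a,b) |
| detour `D` | Σ<sub>a&lt;b</sub> D(a,b) |
| detour-Harary `DH` | Σ<sub>a&lt;b</sub> 1/D(a,b) |

The detour matrix — NP-hard in general — is computed *exactly* by
decomposing the graph into biconnected blocks and composing per-block
longest paths along the block–cut tree; blocks are searched exhaustively
under an explicit budget, so drug-sized graphs (≤ ~70 vertices in all-H
mode) finish in milliseconds and pathological inputs fail loudly instead of
being approximated.

The indices are then related to six physicochemical properties (boiling
point, enthalpy of vaporization, flash point, molar refractivity,
polarizability, molar volume) by Pearson correlation, single-descriptor
ordinary least squares `u = v + w·t`, and ε-insensitive support vector
regression with the RBF kernel, tuned by grid search (C ∈ {10, 50, 100,
500}, ε ∈ {0.1 … 0.5}, γ ∈ {scale, auto}) with 5-fold cross-validation on
an 80 % training split. Model quality is reported as R² and RMSE.

The package ships the full 15-drug study dataset (names, curated SMILES
locked by molecular-formula checks, property table, published reference
index tables with per-cell reliability flags) and a synthetic-data module
that generates molecule-like random graphs and property vectors with known
structure, so every stage is testable offline.

## Worked example

```python
import tcaqspr as t

mol = t.parse_smiles("CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1", name="Diazepam")
g = t.build_graph(mol, t.HydrogenMode.HEAVY_ONLY)
pm = t.pair_matrices(g)
v = t.compute_index_vector(pm.d, pm.D)
print(f"n={g.n}  W={v.W:.0f}  WW={v.WW:.0f}  H={v.H:.4f}  D={v.D:.0f}  DH={v.DH:.4f}")

props = t.load_properties()
ref = t.load_reference_indices("heavy")
f = t.fit_lr(ref.values["H"], props["BP"], "BP", "H", "heavy")
print(f"BP ~ Harary (heavy): u = {f.intercept:.4f} + {f.slope:.4f} t,"
      f"  R2={f.r2:.4f}, RMSE={f.rmse:.4f}")
```

prints

```
n=20  W=726  WW=2077  H=69.4905  D=1901  DH=24.9069
BP ~ Harary (heavy): u = -19.4084 + 6.0931 t,  R2=0.6692, RMSE=37.3973
```

i.e. diazepam's 20-vertex H-suppressed graph has Wiener index 726 and
Harary index 69.4905, and across the 15 drugs the Harary index explains
about 67 % of the variance in boiling point with a typical error of 37
degrees.

## Command line

```sh
tcaqspr compute-indices --fixture --mode both --out run/
tcaqspr correlate --mode both --out run/
tcaqspr fit-lr --mode both --out run/
tcaqspr tune-svr --mode both --seed 42 --out run/
tcaqspr reproduce --seed 42 --out run/
```

`reproduce` writes the complete report bundle: recomputed index tables for
both modes, a cell-level discrepancy report against the published reference
tables, 5×6 correlation matrices, the full LR and tuned-SVR reports with
per-property best models, actual-vs-predicted values per property, and a
JSON manifest. Reruns with the same seed are byte-identical.

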