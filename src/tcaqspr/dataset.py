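"""The 15-drug study dataset: identities, SMILES, properties, reference tables.

The fixtures ship with the package as plain CSV:

* ``drugs.csv`` — drug name, three-letter abbreviation, molecular formula,
  curated SMILES, and six physicochemical properties: boiling point (BP),
  enthalpy of vaporization (E), flash point (FP), molar refractivity (MR),
  polarizability (P) and molar volume (MV).  Property values are treated as
  unitless reals for modelling.
* ``reference_indices_heavy.csv`` / ``reference_indices_all_h.csv`` — the
  published reference values of the five topological indices per hydrogen
  mode, transcribed verbatim, with per-cell ``suspect`` annotations for the
  H-suppressed entries that the H-suppressed computation provably cannot
  reproduce (see each row's ``note`` and the discrepancy report).

Every SMILES is locked by a molecular-formula cross-check at load time, so a
wrong or corrupted structure fails loudly rather than silently shifting every
downstream number.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .molgraph import HydrogenMode, Molecule, parse_smiles
from .topo_indices import INDEX_NAMES

__all__ = [
    "PROPERTY_NAMES",
    "DrugRecord",
    "ReferenceIndexTable",
    "FixtureIntegrityError",
    "load_dataset",
    "load_properties",
    "load_reference_indices",
    "compare_to_reference",
]

#: Property column order, matching the published property table.
PROPERTY_NAMES: tuple[str, ...] = ("BP", "E", "FP", "MR", "P", "MV")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture failed its internal consistency check."""


@dataclass(frozen=True)
class DrugRecord:
    """One drug: identity, structure, and six property values."""

    name: str
    abbreviation: str
    formula: str
    smiles: str
    BP: float
    E: float
    FP: float
    MR: float
    P: float
    MV: float
    molecule: Molecule

    def property_value(self, prop: str) -> float:
        if prop not in PROPERTY_NAMES:
            raise KeyError(f"unknown property {prop!r}")
        return float(getattr(self, prop))


@dataclass(frozen=True)
class ReferenceIndexTable:
    """Published index values for one hydrogen mode, with suspect flags.

    ``suspect`` maps a drug abbreviation to the index columns whose printed
    values are flagged as irreproducible; an absent key means the row is
    fully trusted.  Used only by tests and the discrepancy report, never as a
    computation input for the index pipeline itself.
    """

    mode: HydrogenMode
    values: pd.DataFrame
    suspect: dict[str, frozenset[str]]
    notes: dict[str, str]

    def trusted_cells(self) -> list[tuple[str, str]]:
        """(abbreviation, index name) pairs whose printed value is trusted."""
        out = []
        for abbr in self.values.index:
            flagged = self.suspect.get(abbr, frozenset())
            out.extend((abbr, ix) for ix in INDEX_NAMES if ix not in flagged)
        return out


def _read_fixture(filename: str) -> pd.DataFrame:
    with resources.files("tcaqspr.data").joinpath(filename).open("r") as fh:
        return pd.read_csv(fh, keep_default_na=False)


def _parse_formula(formula: str) -> Counter:
    counts: Counter = Counter()
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FixtureIntegrityError(f"malformed formula {formula!r}")
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise FixtureIntegrityError(f"malformed formula {formula!r}")
    return counts


def _check_formula(mol: Molecule, formula: str, name: str) -> None:
    expected = _parse_formula(formula)
    got: Counter = Counter()
    for sym, h in mol.atoms:
        got[sym] += 1
        got["H"] += h
    got += Counter()  # drop zero entries
    if got != expected:
        raise FixtureIntegrityError(
            f"SMILES/formula mismatch for {name}: formula {formula} implies "
            f"{dict(expected)}, SMILES gives {dict(got)}"
        )


def load_dataset() -> list[DrugRecord]:
    """Load and validate the 15 drug records.

    Each SMILES is parsed and its element counts are checked against the
    declared molecular formula; any mismatch raises
    :class:`FixtureIntegrityError` naming the drug.
    """
    df = _read_fixture("drugs.csv")
    records = []
    for row in df.itertuples(index=False):
        mol = parse_smiles(row.smiles, name=row.name, abbreviation=row.abbreviation)
        _check_formula(mol, row.formula, row.name)
        records.append(
            DrugRecord(
                name=row.name,
                abbreviation=row.abbreviation,
                formula=row.formula,
                smiles=row.smiles,
                BP=float(row.BP),
                E=float(row.E),
                FP=float(row.FP),
                MR=float(row.MR),
                P=float(row.P),
                MV=float(row.MV),
                molecule=mol,
            )
        )
    abbrs = [r.abbreviation for r in records]
    if len(set(abbrs)) != len(abbrs):
        raise FixtureIntegrityError("duplicate drug abbreviations in fixture")
    return records


def load_properties() -> pd.DataFrame:
    """Property table: rows keyed by abbreviation, columns ``BP .. MV``."""
    records = load_dataset()
    return pd.DataFrame(
        {p: [r.property_value(p) for r in records] for p in PROPERTY_NAMES},
        index=[r.abbreviation for r in records],
    )


def load_reference_indices(mode: HydrogenMode | str) -> ReferenceIndexTable:
    """Published index table for ``mode``, verbatim, with suspect flags."""
    mode = HydrogenMode(mode)
    filename = (
        "reference_indices_heavy.csv"
        if mode is HydrogenMode.HEAVY_ONLY
        else "reference_indices_all_h.csv"
    )
    df = _read_fixture(filename)
    values = df.set_index("abbreviation")[list(INDEX_NAMES)].astype(float)
    suspect = {}
    notes = {}
    for row in df.itertuples(index=False):
        if row.suspect:
            cols = frozenset(row.suspect.split(";"))
            unknown = cols - set(INDEX_NAMES)
            if unknown:
                raise FixtureIntegrityError(f"unknown suspect columns {unknown}")
            suspect[row.abbreviation] = cols
        if row.note:
            notes[row.abbreviation] = row.note
    return ReferenceIndexTable(mode=mode, values=values, suspect=suspect, notes=notes)


def compare_to_reference(
    computed: pd.DataFrame, mode: HydrogenMode | str, atol: float = 5e-5
) -> pd.DataFrame:
    """Cell-by-cell discrepancy report of a computed table vs. the reference.

    Returns a tidy frame with one row per (drug, index) cell: the printed and
    recomputed values, whether they agree within ``atol`` (half a unit in the
    4th decimal place), the suspect flag, and the fixture's note for flagged
    rows.
    """
    ref = load_reference_indices(mode)
    rows = []
    for abbr in ref.values.index:
        flagged = ref.suspect.get(abbr, frozenset())
        for ix in INDEX_NAMES:
            printed = ref.values.at[abbr, ix]
            value = float(computed.at[abbr, ix]) if abbr in computed.index else float("nan")
            rows.append(
                {
                    "abbreviation": abbr,
                    "mode": HydrogenMode(mode).value,
                    "index": ix,
                    "printed": printed,
                    "computed": value,
                    "match": bool(abs(value - printed) <= atol),
                    "suspect": ix in flagged,
                    "note": ref.notes.get(abbr, "") if ix in flagged else "",
                }
            )
    return pd.DataFrame(rows)
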