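"""Suspect list, reference-standard registry, and diagnostic-fragment library.

Three small delimited-text inputs drive the screening:

* a **suspect list** of PFAS names and elemental formulas (emulating large
  public PFAS mass lists) from which theoretical [M-H]- m/z are computed;
* a **reference-standard registry** mapping the authentic standards run
  alongside the samples to their expected retention times (the basis of
  Level-1 confirmation);
* a **fragment library** mapping a compound name or class label to the
  diagnostic product-ion formulas expected in its MS2 spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .chem import (
    ElementalFormula,
    FormulaError,
    fragment_mz,
    monoisotopic_mass,
    mz_deprotonated,
    parse_formula,
    ppm_error,
)

__all__ = [
    "SuspectEntry",
    "ReferenceStandard",
    "FragmentLibraryEntry",
    "FragmentLibrary",
    "StandardsRegistry",
    "load_suspect_list",
    "load_standards",
    "load_fragment_library",
    "filter_mass_range",
]


@dataclass(frozen=True)
class SuspectEntry:
    name: str
    formula: ElementalFormula
    neutral_mass: float
    theoretical_mz: float
    class_label: Optional[str] = None
    cas: Optional[str] = None

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula: ElementalFormula | str,
        class_label: Optional[str] = None,
        cas: Optional[str] = None,
    ) -> "SuspectEntry":
        if isinstance(formula, str):
            formula = parse_formula(formula)
        neutral = monoisotopic_mass(formula)
        return cls(
            name=name,
            formula=formula,
            neutral_mass=neutral,
            theoretical_mz=mz_deprotonated(neutral),
            class_label=class_label,
            cas=cas,
        )


@dataclass(frozen=True)
class ReferenceStandard:
    name: str
    formula: ElementalFormula
    expected_rt: float  # minutes
    fragment_formulas: Tuple[str, ...] = ()

    @property
    def theoretical_mz(self) -> float:
        return mz_deprotonated(monoisotopic_mass(self.formula))


@dataclass(frozen=True)
class FragmentLibraryEntry:
    owner: str  # compound name or class label
    fragment_formula: ElementalFormula
    provenance: str = "literature"

    @property
    def mz(self) -> float:
        return fragment_mz(self.fragment_formula)


def _read_table(path, required: Sequence[str], what: str) -> pd.DataFrame:
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.EmptyDataError, csv.Error):
        raise ValueError(f"empty or malformed {what} file: {path}") from None
    if df.empty:
        raise ValueError(f"empty {what} file: {path}")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path} lacks columns {missing}")
    return df


def load_suspect_list(
    path,
    column_map: Optional[Dict[str, str]] = None,
) -> List[SuspectEntry]:
    """Load a suspect list from CSV/TSV with at least name + formula columns.

    ``column_map`` renames foreign dialects onto the native schema
    (name, formula, optional class, cas, neutral_mass).  Neutral mass is
    recomputed from the formula when absent, and validated (1e-4 Da) when
    present.  Duplicate (name, formula) rows collapse with a warning;
    isomeric formulas under different names are all retained.
    """
    df = _read_table(path, (), "suspect list")
    if column_map:
        df = df.rename(columns={k.lower(): v for k, v in column_map.items()})
    for col in ("name", "formula"):
        if col not in df.columns:
            raise ValueError(f"suspect list {path} lacks column {col!r}")

    entries: List[SuspectEntry] = []
    seen: set = set()
    errors: List[str] = []
    for idx, row in df.iterrows():
        try:
            formula = parse_formula(str(row["formula"]))
        except FormulaError as exc:
            errors.append(f"row {idx}: {exc}")
            continue
        key = (str(row["name"]), str(formula))
        if key in seen:
            warnings.warn(
                f"duplicate suspect entry collapsed: {key[0]} {key[1]}",
                stacklevel=2,
            )
            continue
        seen.add(key)
        entry = SuspectEntry.from_formula(
            name=str(row["name"]),
            formula=formula,
            class_label=(
                str(row["class"]) if "class" in df.columns and pd.notna(row.get("class")) else None
            ),
            cas=(
                str(row["cas"]) if "cas" in df.columns and pd.notna(row.get("cas")) else None
            ),
        )
        if "neutral_mass" in df.columns and pd.notna(row.get("neutral_mass")):
            stated = float(row["neutral_mass"])
            if abs(stated - entry.neutral_mass) > 1e-4:
                errors.append(
                    f"row {idx}: stated neutral mass {stated} differs from "
                    f"formula mass {entry.neutral_mass:.6f} by >1e-4 Da"
                )
                continue
        entries.append(entry)
    if errors:
        raise ValueError(
            "suspect list parse errors:\n  " + "\n  ".join(errors)
        )
    return entries


def filter_mass_range(
    entries: Iterable[SuspectEntry], max_mass: float
) -> List[SuspectEntry]:
    """Retain suspects with neutral mass <= max_mass (inclusive boundary).

    Mirrors capping a suspect list at the top of the MS1 scan range.
    Order-preserving and idempotent.
    """
    if max_mass <= 0:
        raise ValueError("max_mass must be positive")
    return [e for e in entries if e.neutral_mass <= max_mass]


@dataclass
class StandardsRegistry:
    """Reference standards keyed for tolerance lookup by theoretical m/z."""

    standards: List[ReferenceStandard] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.standards)

    def __iter__(self):
        return iter(self.standards)

    def lookup_mz(self, mz: float, tol_ppm: float = 5.0) -> List[ReferenceStandard]:
        """All standards whose theoretical m/z is within tol_ppm of ``mz``."""
        return [
            s
            for s in self.standards
            if abs(ppm_error(mz, s.theoretical_mz)) <= tol_ppm
        ]

    def lookup_formula(self, formula: ElementalFormula) -> Optional[ReferenceStandard]:
        for s in self.standards:
            if s.formula.counts == formula.counts:
                return s
        return None


def load_standards(path) -> StandardsRegistry:
    """Load the reference-standard registry (name, formula, expected_rt).

    An optional ``fragments`` column holds a ';'-separated list of product-ion
    formulas observed for the standard.  A missing RT is an error: retention
    confirmation is the registry's purpose.
    """
    df = _read_table(path, ("name", "formula", "expected_rt"), "standards")
    standards = []
    for idx, row in df.iterrows():
        if pd.isna(row["expected_rt"]):
            raise ValueError(f"standards file {path} row {idx}: missing expected_rt")
        frags: Tuple[str, ...] = ()
        if "fragments" in df.columns and pd.notna(row.get("fragments")):
            frags = tuple(
                f.strip() for f in str(row["fragments"]).split(";") if f.strip()
            )
        standards.append(
            ReferenceStandard(
                name=str(row["name"]),
                formula=parse_formula(str(row["formula"])),
                expected_rt=float(row["expected_rt"]),
                fragment_formulas=frags,
            )
        )
    return StandardsRegistry(standards)


@dataclass
class FragmentLibrary:
    """Per-owner diagnostic fragment lookup.

    Owners are compound names (structure-specific evidence) or class labels
    such as ``PFSA`` (class-level evidence).  Lookups for unknown owners
    return empty sets rather than raising.
    """

    entries: List[FragmentLibraryEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def fragments_for(self, owner: str) -> List[FragmentLibraryEntry]:
        return [e for e in self.entries if e.owner == owner]

    def fragments_for_suspect(
        self, suspect: SuspectEntry
    ) -> List[FragmentLibraryEntry]:
        """Union of the suspect's own entry and its class entry."""
        out = self.fragments_for(suspect.name)
        if suspect.class_label:
            names = {str(e.fragment_formula) for e in out}
            out += [
                e
                for e in self.fragments_for(suspect.class_label)
                if str(e.fragment_formula) not in names
            ]
        return out

    def validate_against(self, suspects: Iterable[SuspectEntry]) -> None:
        """Reject fragments heavier than their owner compound's precursor."""
        by_name = {s.name: s for s in suspects}
        for e in self.entries:
            owner = by_name.get(e.owner)
            if owner is not None and e.mz >= owner.theoretical_mz:
                raise ValueError(
                    f"fragment {e.fragment_formula} ({e.mz:.4f}) is not lighter "
                    f"than precursor of {e.owner} ({owner.theoretical_mz:.4f})"
                )


def load_fragment_library(path) -> FragmentLibrary:
    """Load the fragment library: columns owner, fragment, optional provenance."""
    df = _read_table(path, ("owner", "fragment"), "fragment library")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            FragmentLibraryEntry(
                owner=str(row["owner"]),
                fragment_formula=parse_formula(str(row["fragment"])),
                provenance=(
                    str(row["provenance"])
                    if "provenance" in df.columns and pd.notna(row.get("provenance"))
                    else "literature"
                ),
            )
        )
    return FragmentLibrary(entries)
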