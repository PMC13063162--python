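"""Elemental-formula algebra and CF2 Kendrick mass arithmetic.

Everything downstream of the mass spectrometer reduces to a handful of exact
numbers: monoisotopic element masses, the proton and electron masses, and the
exact mass of the CF2 repeat unit.  They are frozen here so that every module
computes against the same table.

Conventions
-----------
* ``[M-H]-`` m/z is the neutral monoisotopic mass minus the mass of a proton
  (1.00727646 Da); the ionising electron stays on the anion.
* Fragment anions are intact formulas plus one electron mass (no proton loss).
* Kendrick masses are CF2-normalised: ``KM = m/z * 50 / 49.9968064``; the
  Kendrick mass defect is ``round(KM) - KM`` with round-half-to-even, so
  members of a CF2 homologous series share a KMD.  Negative KMDs are legal
  (the 1H-perfluoroalkane series sits just below zero).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Mapping

__all__ = [
    "FormulaError",
    "ElementalFormula",
    "KMDPoint",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "CF2_EXACT",
    "CF2_NOMINAL",
    "parse_formula",
    "monoisotopic_mass",
    "mz_deprotonated",
    "fragment_mz",
    "ppm_error",
    "kendrick_mass",
    "kendrick_mass_defect",
]

# IUPAC/CODATA monoisotopic masses (Da) of the most abundant isotope.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,  # carbon-12 definition
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "S": 31.9720707,
    "P": 30.97376151,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "I": 126.904468,
    "Na": 22.98976928,
    "K": 38.9637069,
}

PROTON_MASS = 1.00727646  # Da
ELECTRON_MASS = 0.00054858  # Da

#: Exact mass of one CF2 repeat unit (== mass(C) + 2*mass(F)).
CF2_EXACT = 49.9968064
#: Nominal (integer) mass assigned to CF2 in the Kendrick scale.
CF2_NOMINAL = 50


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula strings."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map, e.g. ``{C: 4, H: 1, F: 9, O: 3, S: 1}``.

    Counts are strictly positive; at least one element is present.  The text
    form uses Hill order (C, H, then alphabetical) and round-trips through
    :func:`parse_formula`.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("formula must contain at least one element")
        for element, count in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {element!r}")
            if count < 1:
                raise FormulaError(
                    f"count for {element} must be >= 1, got {count}"
                )
        # freeze the mapping so the dataclass is hashable/safe to share
        object.__setattr__(self, "counts", dict(self.counts))

    def __str__(self) -> str:
        symbols = sorted(self.counts)
        ordered = []
        if "C" in self.counts:
            ordered.append("C")
            symbols.remove("C")
            if "H" in self.counts:
                ordered.append("H")
                symbols.remove("H")
        ordered.extend(symbols)
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in ordered
        )

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C4HF9O3S"``.

    Implicit count 1 is allowed (``"C4HF9O3S"`` -> H:1).  Repeated element
    tokens accumulate.  Empty strings, unknown symbols, and explicit zero
    counts raise :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at offset {pos}")
        element, digits = m.group(1), m.group(2)
        count = int(digits) if digits else 1
        if digits and count == 0:
            raise FormulaError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Neutral monoisotopic mass (Da): sum of count x element mass."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items())


def mz_deprotonated(neutral_mass: float) -> float:
    """[M-H]- m/z from a neutral mass: subtract one proton mass.

    The electron gained on ionisation is retained, which reproduces the
    printed theoretical values for deprotonated PFAS anions.
    """
    if neutral_mass <= PROTON_MASS:
        raise ValueError(
            f"neutral mass {neutral_mass} Da too small to deprotonate"
        )
    return neutral_mass - PROTON_MASS


def fragment_mz(formula: ElementalFormula | str) -> float:
    """m/z of a singly charged intact fragment anion: mass + one electron.

    Used for diagnostic product ions such as SO3- or C2F5- whose formulas
    describe the whole anion (no proton loss applied).
    """
    return monoisotopic_mass(formula) + ELECTRON_MASS


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6


def kendrick_mass(measured_mz: float) -> float:
    """CF2-normalised Kendrick mass: m/z x 50 / 49.9968064."""
    if measured_mz <= 0:
        raise ValueError("m/z must be positive")
    return measured_mz * CF2_NOMINAL / CF2_EXACT


@dataclass(frozen=True)
class KMDPoint:
    """A point on the CF2 Kendrick mass-defect plot."""

    measured_mz: float
    kendrick_mass: float
    kmd: float


def kendrick_mass_defect(measured_mz: float) -> KMDPoint:
    """CF2 Kendrick mass defect: ``round(KM) - KM`` (half-to-even).

    CF2 homologs share the same KMD, so horizontal bands on an m/z-vs-KMD
    plot reveal homologous series.
    """
    km = kendrick_mass(measured_mz)
    kmd = round(km) - km
    return KMDPoint(measured_mz=measured_mz, kendrick_mass=km, kmd=kmd)
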