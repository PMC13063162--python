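"""Bundled catalog: 11 PFAS identified in AFFF-impacted groundwater.

This catalog encodes the benchmark identification set the package ships as
its reference scenario: eleven PFAS across three groundwater samples from
AFFF-impacted sites, spanning four classes (perfluoroalkanesulfonic acids,
perfluoroalkanesulfonamides, a fluorotelomer sulfonate, and
1H-perfluoroalkanes).  For each compound it records the elemental formula,
retention time, per-sample signed mass error (ppm), diagnostic MS2 fragment
formulas, and — where a published measured product-ion m/z exists — that
observation, used both to seed realistic fragment mass offsets in the
synthetic generator and to sanity-check the MS2 match tolerance.

Five compounds have authentic reference standards (Level-1 confirmations);
their expected RTs sit slightly off the sample apexes by the reported
delta-RT.  The suspect list additionally carries five decoy PFAS that are
*not* present as genuine peaks; the synthetic scenario plants one
failure-mode decoy peak per sample on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .chem import fragment_mz, monoisotopic_mass, mz_deprotonated, parse_formula

__all__ = [
    "CatalogCompound",
    "COMPOUNDS",
    "DECOY_SUSPECTS",
    "FRAGMENT_OBSERVATIONS",
    "SAMPLES",
    "suspect_rows",
    "standard_rows",
    "fragment_rows",
    "write_libraries",
]

SAMPLES = ("Sample3", "Sample4", "Sample5")


@dataclass(frozen=True)
class CatalogCompound:
    name: str
    pfas_class: str
    formula: str
    rt: float  # apex retention time, minutes
    #: sample id -> signed mass error (ppm) of the measured precursor
    samples: Dict[str, float]
    #: diagnostic MS2 fragments: formula -> published measured m/z (or None)
    fragments: Dict[str, Optional[float]]
    #: expected RT of the authentic standard (None = no standard available)
    standard_rt: Optional[float] = None

    @property
    def theoretical_mz(self) -> float:
        return mz_deprotonated(monoisotopic_mass(parse_formula(self.formula)))


COMPOUNDS: Tuple[CatalogCompound, ...] = (
    CatalogCompound(
        "PFBS", "PFSA", "C4HF9O3S", 3.8,
        {"Sample3": 0.8273, "Sample5": -0.1936},
        {"FO3S": None, "SO3": None},
        standard_rt=3.76,  # sample apex 0.04 min later than the standard
    ),
    CatalogCompound(
        "PFPeS", "PFSA", "C5HF11O3S", 4.3,
        {"Sample3": 0.9737, "Sample5": 0.3178},
        {"C2F5": None, "FO3S": None, "SO3": None},
        standard_rt=4.27,
    ),
    CatalogCompound(
        "PFHxS", "PFSA", "C6HF13O3S", 4.8,
        {"Sample3": 1.007, "Sample4": 0.7392, "Sample5": 0.0125},
        {"C3F7": None, "FO3S": None, "SO3": None},
        standard_rt=4.76,
    ),
    CatalogCompound(
        "PFOS", "PFSA", "C8HF17O3S", 6.6,
        {"Sample5": 0.4925},
        {"C8F17": None, "FO3S": None, "SO3": None},
        standard_rt=6.52,
    ),
    CatalogCompound(
        "6:2 FTS", "FTS", "C8H5F13O3S", 5.5,
        {"Sample5": 0.2877},
        {
            "C8H3F12O3S": None,
            "C8H2F11O3S": None,
            "C7F11": None,
            "C4H4O2F3": None,
            "HO3S": None,
            "SO3": None,
        },
        standard_rt=5.43,
    ),
    CatalogCompound(
        "PFPrS", "PFSA", "C3HF7O3S", 3.4,
        {"Sample5": -0.7054},
        {"C2F5": 118.9911, "FO3S": 98.9544, "SO3": 79.9559},
    ),
    CatalogCompound(
        "FPrSA", "FASA", "C3H2F7NO2S", 3.6,
        {"Sample5": -0.8476},
        {"C3F7": 168.9884, "FO2S": 82.9595, "NO2S": 77.9641},
    ),
    CatalogCompound(
        "FBSA", "FASA", "C4H2F9NO2S", 4.1,
        {"Sample3": -0.139, "Sample5": -0.139},
        {"C4F9": 218.9857, "C2F5": 118.9915, "NO2S": 77.9641},
    ),
    CatalogCompound(
        "FHxSA", "FASA", "C6H2F13NO2S", 5.5,
        {"Sample3": 0.8843, "Sample5": -0.036},
        {"C6F13": 318.9791, "C4F9": 218.9848, "NO2S": 77.9641},
    ),
    CatalogCompound(
        "1H-perfluoropentane", "perfluoroalkanes", "C5HF11", 4.3,
        {"Sample3": 0.9884, "Sample5": 0.1374},
        {"C2F5": 118.9912, "CF3": 68.9943},
    ),
    CatalogCompound(
        "1H-perfluoroheptane", "perfluoroalkanes", "C7HF15", 5.6,
        {"Sample4": 0.6428, "Sample5": 0.1879},
        {"C4F9": 218.9857, "C3F7": 168.9884, "C2F5": 118.9912},
    ),
)

#: decoy suspect-list entries: plausible PFAS with no genuine peak in any
#: sample; the synthetic scenario plants one failure-mode peak per sample.
DECOY_SUSPECTS: Tuple[Tuple[str, str, str], ...] = (
    ("PFHpS", "PFSA", "C7HF15O3S"),   # sub-threshold peak area
    ("PFDS", "PFSA", "C10HF21O3S"),   # high-noise channel, S/N < 50
    ("PFOA", "PFCA", "C8HF15O2"),     # blank contaminant
    ("PFNA", "PFCA", "C9HF17O2"),     # present in one replicate only
    ("PFHxA", "PFCA", "C6HF11O2"),    # mass error beyond 5 ppm
)


def _observations() -> List[Tuple[str, str, float, float]]:
    out = []
    for c in COMPOUNDS:
        for frag, obs in c.fragments.items():
            if obs is not None:
                out.append((c.name, frag, obs, fragment_mz(frag)))
    return out


#: (compound, fragment formula, published measured m/z, theoretical anion m/z)
FRAGMENT_OBSERVATIONS: Tuple[Tuple[str, str, float, float], ...] = tuple(_observations())


def suspect_rows() -> List[dict]:
    """Suspect-list rows: the 11 catalog compounds plus the 5 decoys."""
    rows = [
        {"name": c.name, "formula": c.formula, "class": c.pfas_class}
        for c in COMPOUNDS
    ]
    rows += [
        {"name": n, "formula": f, "class": cls} for n, cls, f in DECOY_SUSPECTS
    ]
    return rows


def standard_rows() -> List[dict]:
    """Reference-standard rows for the five standard-confirmed compounds."""
    return [
        {
            "name": c.name,
            "formula": c.formula,
            "expected_rt": c.standard_rt,
            "fragments": ";".join(c.fragments),
        }
        for c in COMPOUNDS
        if c.standard_rt is not None
    ]


def fragment_rows() -> List[dict]:
    """Fragment-library rows keyed by compound name."""
    return [
        {"owner": c.name, "fragment": frag, "provenance": "literature"}
        for c in COMPOUNDS
        for frag in c.fragments
    ]


def write_libraries(outdir) -> Dict[str, str]:
    """Write suspects.csv, standards.csv, fragments.csv; return their paths."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for fname, rows in (
        ("suspects.csv", suspect_rows()),
        ("standards.csv", standard_rows()),
        ("fragments.csv", fragment_rows()),
    ):
        p = outdir / fname
        pd.DataFrame(rows).to_csv(p, index=False)
        paths[fname.split(".")[0]] = str(p)
    return paths
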