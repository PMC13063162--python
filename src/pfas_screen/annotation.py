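"""MS2 diagnostic-fragment matching and identification confidence levels.

Candidates that survive MS1 screening are confirmed against a curated
fragment library: for each expected product ion, the nearest observed MS2
centroid within tolerance counts as a match.  The MS2 tolerance defaults to
``max(5 mDa, 20 ppm)`` — wider than the 5 ppm MS1 tolerance because product
ions from lower-resolution MS2 scans routinely deviate from theory by
~1-1.5 mDa, which at m/z < 200 is far beyond 5 ppm.

Confidence levels follow the 1-5 identification scale for PFAS screening:

* **1** — retention time matches an authentic standard and at least two of
  the standard's fragments are observed;
* **2** — no standard, but >= 2 diagnostic fragments consistent with a
  single proposed structure (the suspect's own or class fragment set);
* **3** — >= 2 isomeric suspects are indistinguishable (same formula, same
  matched fragments);
* **4** — formula-level support only (a single matched fragment, or only
  generic structure-ambiguous fragments);
* **5** — accurate mass only (no MS2 spectrum or no fragment match).

The final report keeps candidates with at least one MS2 spectrum and at
least two fragment matches; Level 5 and single-fragment candidates are
recorded but not reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .chem import ElementalFormula, fragment_mz, parse_formula, ppm_error
from .msio import CentroidSpectrum, Run, ms2_for_precursor
from .screening import CandidateHit, ScreeningResult
from .suspects import FragmentLibrary, FragmentLibraryEntry

__all__ = [
    "AnnotationConfig",
    "FragmentMatch",
    "AnnotatedCandidate",
    "match_tolerance",
    "annotate_fragments",
    "assign_confidence",
    "annotate_all",
]

#: owner label treated as generic, structure-ambiguous evidence
GENERIC_OWNER = "PFAS"


@dataclass(frozen=True)
class AnnotationConfig:
    tol_mda: float = 5.0
    tol_ppm: float = 20.0
    rt_pad: float = 0.2  # min added around the peak bounds when pulling MS2


@dataclass(frozen=True)
class FragmentMatch:
    fragment_formula: ElementalFormula
    theoretical_mz: float
    observed_mz: float
    abs_error: float  # Da
    ppm_error: float
    owner: str  # library entry owner that supplied the fragment


@dataclass
class AnnotatedCandidate:
    hit: CandidateHit
    fragment_matches: List[FragmentMatch]
    confidence_level: int
    rationale: str
    n_ms2_spectra: int = 0

    @property
    def reportable(self) -> bool:
        """Report-inclusion contract: >=1 MS2 spectrum and >=2 fragments."""
        return (
            self.n_ms2_spectra >= 1
            and len(self.fragment_matches) >= 2
            and self.confidence_level <= 4
        )


def match_tolerance(theoretical_mz: float, tol_mda: float = 5.0, tol_ppm: float = 20.0) -> float:
    """Absolute MS2 match tolerance in Da: max of the mDa and ppm windows."""
    return max(tol_mda * 1e-3, tol_ppm * 1e-6 * theoretical_mz)


def annotate_fragments(
    spectrum: CentroidSpectrum,
    owner_fragments: Sequence[FragmentLibraryEntry],
    tol_mda: float = 5.0,
    tol_ppm: float = 20.0,
) -> List[FragmentMatch]:
    """Match library fragments to the nearest observed centroid in tolerance.

    At most one match per library fragment; ties break on smallest absolute
    error.  Distinct library fragments may legitimately claim the same
    centroid when their theoretical masses are close.
    """
    if spectrum.ms_level != 2:
        raise ValueError("fragment annotation requires an MS2 spectrum")
    matches: List[FragmentMatch] = []
    mz = spectrum.mz
    for entry in owner_fragments:
        theo = entry.mz
        tol = match_tolerance(theo, tol_mda, tol_ppm)
        if mz.size == 0:
            continue
        errors = abs(mz - theo)
        best = int(errors.argmin())
        if errors[best] <= tol:
            matches.append(
                FragmentMatch(
                    fragment_formula=entry.fragment_formula,
                    theoretical_mz=theo,
                    observed_mz=float(mz[best]),
                    abs_error=float(errors[best]),
                    ppm_error=ppm_error(float(mz[best]), theo),
                    owner=entry.owner,
                )
            )
    return matches


def _merge_matches(groups: Iterable[List[FragmentMatch]]) -> List[FragmentMatch]:
    """Best match per library fragment across several spectra."""
    best: Dict[str, FragmentMatch] = {}
    for group in groups:
        for m in group:
            key = str(m.fragment_formula)
            if key not in best or m.abs_error < best[key].abs_error:
                best[key] = m
    return sorted(best.values(), key=lambda m: m.theoretical_mz)


def assign_confidence(
    hit: CandidateHit,
    matches: List[FragmentMatch],
    n_ms2_spectra: int,
    isomer_ambiguous: bool = False,
) -> AnnotatedCandidate:
    """Apply the Level 1-5 rule table to one screened candidate."""
    name = hit.suspect.name
    frag_names = sorted(str(m.fragment_formula) for m in matches)

    if n_ms2_spectra == 0:
        level, why = 5, "no MS2 spectrum acquired for this precursor"
    elif len(matches) == 0:
        level, why = 5, "MS2 acquired but no library fragment matched"
    elif len(matches) == 1:
        level, why = 4, (
            f"single fragment match ({frag_names[0]}): formula-level support only"
        )
    elif isomer_ambiguous:
        level, why = 3, (
            f"fragments {frag_names} shared by isomeric suspects; tentative"
        )
    elif hit.rt_standard_match and hit.standard is not None:
        # canonicalize: library/standard files may write e.g. SO3 for O3S
        std_set = {
            str(parse_formula(f)) for f in hit.standard.fragment_formulas
        }
        n_std = sum(1 for m in matches if str(m.fragment_formula) in std_set)
        if n_std >= 2:
            level, why = 1, (
                f"RT within tolerance of standard {hit.standard.name} and "
                f"{n_std} standard fragments matched ({frag_names})"
            )
        else:
            level, why = 2, (
                f"RT matched standard but only {n_std} standard fragment(s); "
                f"{len(matches)} diagnostic fragments support the structure"
            )
    else:
        specific = [m for m in matches if m.owner != GENERIC_OWNER]
        if len(specific) >= 2:
            level, why = 2, (
                f"{len(matches)} diagnostic fragments consistent with the "
                f"proposed structure ({frag_names})"
            )
        else:
            level, why = 4, (
                "only generic perfluoroalkyl fragments matched; "
                "formula-level support"
            )
    return AnnotatedCandidate(
        hit=hit,
        fragment_matches=matches,
        confidence_level=level,
        rationale=f"{name}: {why}",
        n_ms2_spectra=n_ms2_spectra,
    )


def annotate_all(
    result: ScreeningResult,
    runs: Sequence[Run],
    library: FragmentLibrary,
    config: AnnotationConfig = AnnotationConfig(),
) -> List[AnnotatedCandidate]:
    """Annotate every screened candidate with MS2 evidence and a level.

    MS2 spectra are pulled from the candidate's own sample runs within the
    peak RT bounds padded by ``rt_pad`` minutes; matches from all spectra
    merge, keeping the best observation per library fragment.
    """
    runs_by_sample: Dict[str, List[Run]] = {}
    for run in runs:
        if run.role == "sample":
            runs_by_sample.setdefault(run.sample_id, []).append(run)

    prelim: List[Tuple[CandidateHit, List[FragmentMatch], int]] = []
    for hit in result.candidates:
        frags = library.fragments_for_suspect(hit.suspect)
        lo, hi = hit.rt_bounds
        window = (lo - config.rt_pad, hi + config.rt_pad)
        spectra: List[CentroidSpectrum] = []
        for run in runs_by_sample.get(hit.sample_id, []):
            spectra.extend(ms2_for_precursor(run, hit.measured_mz, window))
        per_spec = [
            annotate_fragments(s, frags, config.tol_mda, config.tol_ppm)
            for s in spectra
        ]
        prelim.append((hit, _merge_matches(per_spec), len(spectra)))

    # isomer ambiguity: same sample + same formula + same matched fragment set
    signature: Dict[Tuple[str, str], List[Tuple[str, frozenset]]] = {}
    for hit, matches, _ in prelim:
        if len(matches) >= 2:
            key = (hit.sample_id, str(hit.suspect.formula))
            signature.setdefault(key, []).append(
                (hit.suspect.name, frozenset(str(m.fragment_formula) for m in matches))
            )

    annotated: List[AnnotatedCandidate] = []
    for hit, matches, n_spec in prelim:
        ambiguous = False
        if len(matches) >= 2:
            key = (hit.sample_id, str(hit.suspect.formula))
            sig = frozenset(str(m.fragment_formula) for m in matches)
            ambiguous = any(
                name != hit.suspect.name and other_sig == sig
                for name, other_sig in signature.get(key, [])
            )
        annotated.append(assign_confidence(hit, matches, n_spec, ambiguous))
    return annotated
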