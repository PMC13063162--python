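"""MS1 suspect matching and quality-control filtering.

The screening stage turns per-run feature lists into per-sample candidate
hits by applying, in a fixed order:

1. area / signal-to-noise thresholds (done upstream in feature building),
2. suspect-list matching at <= 5 ppm (inclusive, signed error recorded),
3. blank elimination: a hit is discarded when a feature in any blank run
   matches its m/z and RT and carries a non-negligible fraction of its area,
4. duplicate-injection concordance: the same suspect must be found in both
   replicate injections at consistent RT,
5. retention-time confirmation against the reference-standard registry
   (a flag, not a filter: it feeds Level-1 confidence assignment).

Strict absence in the blank is relaxed to an area-fraction rule (default
10%) so that trace-level blank noise does not veto genuine detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .chem import ppm_error
from .features import Feature, build_features, filter_features
from .msio import Run
from .suspects import ReferenceStandard, StandardsRegistry, SuspectEntry

__all__ = [
    "ScreeningConfig",
    "CandidateHit",
    "ScreeningResult",
    "match_suspects",
    "apply_blank_filter",
    "apply_replicate_filter",
    "confirm_rt",
    "screen",
    "validate_result",
]


@dataclass(frozen=True)
class ScreeningConfig:
    """Screening thresholds; defaults are the workflow's shipped settings."""

    ppm_tol: float = 5.0
    min_area: float = 100_000.0
    min_snr: float = 50.0
    rt_tol_standard: float = 0.1  # min
    blank_rt_tol: float = 0.2  # min
    blank_area_fraction: float = 0.1
    replicate_rt_tol: float = 0.2  # min
    eic_tol_ppm: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "ppm_tol",
            "min_area",
            "min_snr",
            "rt_tol_standard",
            "blank_rt_tol",
            "blank_area_fraction",
            "replicate_rt_tol",
            "eic_tol_ppm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CandidateHit:
    """A feature <-> suspect match, accumulating QC flags as filters run."""

    suspect: SuspectEntry
    sample_id: str
    features: Tuple[Feature, ...]  # one per replicate once merged
    ppm_error: float
    in_both_replicates: bool = False
    blank_detected: bool = False
    rt_standard_match: bool = False
    standard: Optional[ReferenceStandard] = None

    @property
    def rt_apex(self) -> float:
        return float(np.mean([f.rt_apex for f in self.features]))

    @property
    def measured_mz(self) -> float:
        return float(np.mean([f.mz for f in self.features]))

    @property
    def area(self) -> float:
        return float(np.mean([f.area for f in self.features]))

    @property
    def rt_bounds(self) -> Tuple[float, float]:
        return (
            min(f.rt_left for f in self.features),
            max(f.rt_right for f in self.features),
        )


def match_suspects(
    features: Iterable[Feature],
    suspects: Sequence[SuspectEntry],
    ppm_tol: float = 5.0,
) -> List[CandidateHit]:
    """One hit per (feature, suspect) pair within the ppm tolerance.

    Isomeric suspects sharing a formula all match the same feature;
    disambiguation is deferred to confidence assignment.
    """
    hits: List[CandidateHit] = []
    for feature in features:
        for suspect in suspects:
            err = ppm_error(feature.mz, suspect.theoretical_mz)
            if abs(err) <= ppm_tol:
                hits.append(
                    CandidateHit(
                        suspect=suspect,
                        sample_id=feature.sample_id,
                        features=(feature,),
                        ppm_error=err,
                    )
                )
    return hits


def apply_blank_filter(
    hits: Iterable[CandidateHit],
    blank_features: Sequence[Feature],
    config: ScreeningConfig,
) -> List[CandidateHit]:
    """Drop hits whose m/z + RT appear in a blank at meaningful area.

    A blank feature vetoes a hit when it is within ``ppm_tol`` in m/z,
    ``blank_rt_tol`` in RT, and its area is at least ``blank_area_fraction``
    of the sample feature's area.
    """
    kept: List[CandidateHit] = []
    for hit in hits:
        vetoed = False
        for bf in blank_features:
            if (
                abs(ppm_error(bf.mz, hit.measured_mz)) <= config.ppm_tol
                and abs(bf.rt_apex - hit.rt_apex) <= config.blank_rt_tol
                and bf.area >= config.blank_area_fraction * hit.area
            ):
                vetoed = True
                break
        if not vetoed:
            kept.append(replace(hit, blank_detected=False))
        # vetoed hits are removed outright; the flag on survivors stays False
    return kept


def apply_replicate_filter(
    hits: Iterable[CandidateHit],
    replicates_per_sample: Mapping[str, Set[int]],
    config: ScreeningConfig,
) -> List[CandidateHit]:
    """Keep suspects detected in both duplicate injections at consistent RT.

    Hits for the same (sample, suspect) across replicates merge into a single
    hit carrying both features; the reported ppm error is recomputed from the
    mean measured m/z.  A sample lacking a second replicate is an error.
    """
    for sample, reps in replicates_per_sample.items():
        if len(reps) < 2:
            raise ValueError(
                f"sample {sample!r} lacks a duplicate injection "
                f"(replicates present: {sorted(reps)})"
            )
    grouped: Dict[Tuple[str, str], List[CandidateHit]] = {}
    for hit in hits:
        grouped.setdefault((hit.sample_id, hit.suspect.name), []).append(hit)

    merged: List[CandidateHit] = []
    for (sample, _name), group in grouped.items():
        by_rep: Dict[int, List[CandidateHit]] = {}
        for h in group:
            by_rep.setdefault(h.features[0].replicate, []).append(h)
        if len(by_rep) < 2:
            continue
        reps = sorted(by_rep)
        # best RT-concordant pairing between the first two replicates
        best: Optional[Tuple[float, CandidateHit, CandidateHit]] = None
        for h1 in by_rep[reps[0]]:
            for h2 in by_rep[reps[1]]:
                d = abs(h1.rt_apex - h2.rt_apex)
                if d <= config.replicate_rt_tol and (best is None or d < best[0]):
                    best = (d, h1, h2)
        if best is None:
            continue
        _, h1, h2 = best
        feats = h1.features + h2.features
        mean_mz = float(np.mean([f.mz for f in feats]))
        merged.append(
            replace(
                h1,
                features=feats,
                ppm_error=ppm_error(mean_mz, h1.suspect.theoretical_mz),
                in_both_replicates=True,
            )
        )
    return merged


def confirm_rt(
    hits: Iterable[CandidateHit],
    standards: StandardsRegistry,
    rt_tol: float = 0.1,
) -> List[CandidateHit]:
    """Flag hits whose RT lies within ``rt_tol`` of a same-formula standard."""
    out: List[CandidateHit] = []
    for hit in hits:
        std = standards.lookup_formula(hit.suspect.formula)
        ok = std is not None and abs(hit.rt_apex - std.expected_rt) <= rt_tol
        out.append(replace(hit, rt_standard_match=ok, standard=std if ok else None))
    return out


@dataclass
class ScreeningResult:
    candidates: List[CandidateHit]
    stage_counts: Dict[str, int] = field(default_factory=dict)


def screen(
    runs: Sequence[Run],
    suspects: Sequence[SuspectEntry],
    standards: StandardsRegistry,
    config: ScreeningConfig = ScreeningConfig(),
) -> ScreeningResult:
    """Run the full MS1 screening cascade over a set of runs.

    Stage order: feature building + thresholds -> suspect match -> blank
    elimination -> duplicate-injection concordance -> standard RT flagging.
    Deterministic given identical inputs.
    """
    sample_runs = [r for r in runs if r.role == "sample"]
    blank_runs = [r for r in runs if r.role == "blank"]
    if not sample_runs:
        # a blanks-only (or empty) run set legitimately screens to nothing
        return ScreeningResult(candidates=[], stage_counts={"features_detected": 0})

    targets = [s.theoretical_mz for s in suspects]
    counts: Dict[str, int] = {}

    raw_features: List[Feature] = []
    for run in sample_runs:
        raw_features.extend(build_features(run, targets, config.eic_tol_ppm))
    counts["features_detected"] = len(raw_features)

    kept = filter_features(raw_features, config.min_area, config.min_snr)
    counts["features_after_thresholds"] = len(kept)

    hits = match_suspects(kept, suspects, config.ppm_tol)
    counts["suspect_hits"] = len(hits)

    blank_features: List[Feature] = []
    for run in blank_runs:
        # no area/SNR thresholds on blanks: small blank peaks still veto
        blank_features.extend(build_features(run, targets, config.eic_tol_ppm))
    hits = apply_blank_filter(hits, blank_features, config)
    counts["after_blank_filter"] = len(hits)

    replicates = {}
    for run in sample_runs:
        replicates.setdefault(run.sample_id, set()).add(run.replicate)
    hits = apply_replicate_filter(hits, replicates, config)
    counts["after_replicate_filter"] = len(hits)

    hits = confirm_rt(hits, standards, config.rt_tol_standard)
    counts["rt_confirmed"] = sum(h.rt_standard_match for h in hits)

    hits.sort(key=lambda h: (h.sample_id, h.suspect.theoretical_mz, h.suspect.name))
    return ScreeningResult(candidates=hits, stage_counts=counts)


def validate_result(result: ScreeningResult, config: ScreeningConfig) -> None:
    """Post-hoc check that every surviving hit satisfies all config bounds."""
    for hit in result.candidates:
        assert abs(hit.ppm_error) <= config.ppm_tol, hit
        assert hit.in_both_replicates, hit
        assert all(f.area >= config.min_area for f in hit.features), hit
        assert all(f.snr >= config.min_snr for f in hit.features), hit
        if hit.rt_standard_match:
            assert hit.standard is not None
            assert abs(hit.rt_apex - hit.standard.expected_rt) <= config.rt_tol_standard
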