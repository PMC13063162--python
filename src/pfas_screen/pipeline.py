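"""End-to-end workflow assembly and report writing.

``run_pipeline`` chains the stages — MS1 screening, MS2 annotation with
confidence levels, and CF2 homolog analysis — and collects per-stage counts
for an auditable processing log.  Reports are plain CSV: a candidate table
(one row per sample x compound, mirroring the columns of a published
identification table), a per-fragment match report, and the KMD plot table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from .annotation import AnnotatedCandidate, AnnotationConfig, annotate_all
from .homology import HomologSeries, SeriesPoint, check_rt_trend, group_series, kmd_table
from .msio import Run, load_runs
from .screening import ScreeningConfig, ScreeningResult, screen, validate_result
from .suspects import (
    FragmentLibrary,
    StandardsRegistry,
    SuspectEntry,
    load_fragment_library,
    load_standards,
    load_suspect_list,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_from_paths", "write_reports"]


@dataclass(frozen=True)
class PipelineConfig:
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    kmd_tol: float = 0.002
    spacing_ppm: float = 5.0
    max_suspect_mass: float = 1040.0  # Da; cap at the top of the MS1 range

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            screening=ScreeningConfig(**raw.get("screening", {})),
            annotation=AnnotationConfig(**raw.get("annotation", {})),
            kmd_tol=raw.get("kmd_tol", 0.002),
            spacing_ppm=raw.get("spacing_ppm", 5.0),
            max_suspect_mass=raw.get("max_suspect_mass", 1040.0),
        )


@dataclass
class PipelineResult:
    screening: ScreeningResult
    annotated: List[AnnotatedCandidate]
    reported: List[AnnotatedCandidate]
    series: List[HomologSeries]
    kmd: pd.DataFrame
    stage_counts: Dict[str, int]


def run_pipeline(
    runs: Sequence[Run],
    suspects: Sequence[SuspectEntry],
    standards: StandardsRegistry,
    library: FragmentLibrary,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Screen, annotate, and group; deterministic for identical inputs."""
    from .suspects import filter_mass_range

    suspects = filter_mass_range(suspects, config.max_suspect_mass)
    library.validate_against(suspects)

    result = screen(runs, suspects, standards, config.screening)
    validate_result(result, config.screening)

    annotated = annotate_all(result, runs, library, config.annotation)
    reported = [a for a in annotated if a.reportable]

    points = {}
    for a in reported:
        name = a.hit.suspect.name
        if name not in points:
            points[name] = SeriesPoint(
                label=name,
                mz=a.hit.measured_mz,
                rt=a.hit.rt_apex,
                class_label=a.hit.suspect.class_label,
            )
    series = [
        check_rt_trend(s)
        for s in group_series(list(points.values()), config.kmd_tol, config.spacing_ppm)
    ]
    table = kmd_table(points.values(), config.kmd_tol, config.spacing_ppm)

    counts = dict(result.stage_counts)
    counts["annotated"] = len(annotated)
    counts["reported"] = len(reported)
    counts["unique_compounds"] = len(points)
    counts["homolog_series"] = len(series)
    return PipelineResult(
        screening=result,
        annotated=annotated,
        reported=reported,
        series=series,
        kmd=table,
        stage_counts=counts,
    )


def run_from_paths(
    manifest: str,
    suspects_path: str,
    standards_path: str,
    fragments_path: str,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Convenience entry: load all inputs from files and run the pipeline."""
    runs = load_runs(manifest)
    suspects = load_suspect_list(suspects_path)
    standards = load_standards(standards_path)
    library = load_fragment_library(fragments_path)
    return run_pipeline(runs, suspects, standards, library, config)


def candidates_frame(result: PipelineResult) -> pd.DataFrame:
    """Reported candidates, one row per sample x compound."""
    rows = []
    for a in result.reported:
        h = a.hit
        rows.append(
            {
                "sample": h.sample_id,
                "compound": h.suspect.name,
                "class": h.suspect.class_label,
                "formula": str(h.suspect.formula),
                "theoretical_mz": round(h.suspect.theoretical_mz, 4),
                "measured_mz": round(h.measured_mz, 4),
                "rt": round(h.rt_apex, 2),
                "delta_ppm": round(h.ppm_error, 4),
                "confidence_level": a.confidence_level,
                "rt_standard_match": h.rt_standard_match,
                "n_fragments": len(a.fragment_matches),
                "fragments": ";".join(
                    str(m.fragment_formula) for m in a.fragment_matches
                ),
            }
        )
    cols = [
        "sample", "compound", "class", "formula", "theoretical_mz",
        "measured_mz", "rt", "delta_ppm", "confidence_level",
        "rt_standard_match", "n_fragments", "fragments",
    ]
    return pd.DataFrame(rows, columns=cols)


def fragments_frame(result: PipelineResult) -> pd.DataFrame:
    """Per-candidate MS2 match report (observed vs theoretical m/z)."""
    rows = []
    for a in result.reported:
        for m in a.fragment_matches:
            rows.append(
                {
                    "sample": a.hit.sample_id,
                    "compound": a.hit.suspect.name,
                    "fragment": str(m.fragment_formula),
                    "theoretical_mz": round(m.theoretical_mz, 5),
                    "observed_mz": round(m.observed_mz, 5),
                    "error_mda": round(m.abs_error * 1e3, 3),
                    "error_ppm": round(m.ppm_error, 2),
                }
            )
    cols = [
        "sample", "compound", "fragment", "theoretical_mz",
        "observed_mz", "error_mda", "error_ppm",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_reports(result: PipelineResult, outdir) -> Dict[str, str]:
    """Write candidates.csv, fragments.csv, kmd.csv, and a stage-count log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "candidates": str(outdir / "candidates.csv"),
        "fragments": str(outdir / "fragments.csv"),
        "kmd": str(outdir / "kmd.csv"),
        "log": str(outdir / "pipeline_log.txt"),
    }
    candidates_frame(result).to_csv(paths["candidates"], index=False)
    fragments_frame(result).to_csv(paths["fragments"], index=False)
    result.kmd.to_csv(paths["kmd"], index=False)
    with open(paths["log"], "w") as fh:
        for stage, count in result.stage_counts.items():
            fh.write(f"{stage}: {count}\n")
        for s in result.series:
            members = ", ".join(m.label for m in s.members)
            fh.write(
                f"series kmd={s.shared_kmd:+.4f} class={s.class_label} "
                f"rt_trend_ok={s.rt_trend_ok} members=[{members}]\n"
            )
        for a in result.annotated:
            fh.write(f"CL{a.confidence_level} {a.rationale}\n")
    return paths
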