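"""Seeded synthetic LC-MS/MS scenario generator.

Generates complete, reproducible screening scenarios — duplicate sample
injections, blanks, chromatographic peaks, baseline noise, and DDA-style MS2
spectra — so every pipeline stage is testable without instrument data.

The model of a run:

* MS1 scans on a regular RT grid over the elution window, each holding
  scattered background centroids plus, for every injected channel, one
  centroid at the channel's measured m/z whose intensity is a chemical
  baseline draw plus a Gaussian elution profile;
* measured precursor m/z = theoretical x (1 + ppm_error x 1e-6), with a
  small per-scan jitter emulating scan-to-scan mass-measurement scatter;
* MS2 spectra at apex scans of genuine compounds, holding the configured
  diagnostic fragments displaced from theory by a few mDa (as measured
  product ions typically are at lower MS2 resolution) plus random noise
  peaks, with stepped collision energies recorded as metadata.

Decoy peaks exercise each screening failure mode: sub-threshold area,
sub-threshold S/N (noisy channel), blank contaminant, single-replicate
artifact, and mass error beyond tolerance.  The bundled
:func:`groundwater_scenario` reconstructs the package's reference
identification set: 11 PFAS over three AFFF-impacted groundwater samples
with one decoy of each kind per sample.

All randomness derives from ``numpy.random.SeedSequence(scenario seed,
run identity)``, so regenerating with the same seed is byte-identical.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .catalog import COMPOUNDS, DECOY_SUSPECTS, SAMPLES, write_libraries
from .chem import fragment_mz, monoisotopic_mass, mz_deprotonated, parse_formula
from .msio import CentroidSpectrum, Run, RunSpec, write_manifest, write_mzml

__all__ = [
    "InjectedCompound",
    "InjectedDecoy",
    "SampleSpec",
    "Scenario",
    "groundwater_scenario",
    "build_runs",
    "simulate_runs",
]

DECOY_KINDS = ("sub_area", "sub_snr", "blank_contaminant", "single_replicate", "off_ppm")


@dataclass(frozen=True)
class InjectedCompound:
    """A genuine analyte peak in one sample, with its MS2 fragment set."""

    name: str
    theoretical_mz: float
    rt: float  # minutes
    area: float  # counts x minutes
    ppm: float  # injected signed mass error
    #: (fragment formula, mass offset in mDa applied to the theoretical anion)
    fragments: Tuple[Tuple[str, float], ...] = ()

    @property
    def measured_mz(self) -> float:
        return self.theoretical_mz * (1.0 + self.ppm * 1e-6)


@dataclass(frozen=True)
class InjectedDecoy:
    """A peak engineered to fail exactly one screening rule."""

    kind: str
    name: str
    theoretical_mz: float
    rt: float
    area: float
    ppm: float = 0.0
    baseline_mean: Optional[float] = None  # channel override (sub_snr)
    baseline_sd: Optional[float] = None
    replicates: Tuple[int, ...] = (1, 2)
    in_blank: bool = False

    def __post_init__(self) -> None:
        if self.kind not in DECOY_KINDS:
            raise ValueError(f"unknown decoy kind {self.kind!r}")
        if self.kind == "off_ppm" and abs(self.ppm) <= 5:
            raise ValueError(
                f"off_ppm decoy {self.name!r} needs |ppm| > 5, got {self.ppm}"
            )

    @property
    def measured_mz(self) -> float:
        return self.theoretical_mz * (1.0 + self.ppm * 1e-6)


@dataclass(frozen=True)
class SampleSpec:
    compounds: Tuple[InjectedCompound, ...]
    decoys: Tuple[InjectedDecoy, ...] = ()


@dataclass(frozen=True)
class Scenario:
    samples: Dict[str, SampleSpec]
    seed: int = 7
    rt_span: Tuple[float, float] = (0.0, 8.0)
    scan_spacing: float = 0.01  # min; >= 9 points across a peak
    peak_sigma: float = 0.03  # min
    baseline_mean: float = 2000.0  # chemical baseline on injected channels
    baseline_sd: float = 800.0
    noise_centroids_per_scan: int = 20
    noise_intensity_mean: float = 500.0
    mz_jitter_ppm: float = 0.1  # per-scan scatter of the measured m/z
    ms2_events_per_peak: int = 2  # DDA repeat fragmentation at the apex
    ms2_noise_peaks: int = 4
    isolation_halfwidth: float = 0.5  # Th
    collision_energies: Tuple[float, ...] = (15.0, 30.0, 50.0)
    n_blanks: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.rt_span
        for spec in self.samples.values():
            for c in spec.compounds:
                if not (lo <= c.rt <= hi):
                    raise ValueError(f"{c.name}: RT {c.rt} outside run span {self.rt_span}")
                if abs(c.ppm) > 5:
                    raise ValueError(
                        f"{c.name}: genuine compounds need |ppm| <= 5, got {c.ppm}"
                    )
        self._warn_overlaps()

    def _warn_overlaps(self) -> None:
        for sample, spec in self.samples.items():
            items = list(spec.compounds) + list(spec.decoys)
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    a, b = items[i], items[j]
                    close_rt = abs(a.rt - b.rt) < self.scan_spacing
                    close_mz = (
                        abs(a.theoretical_mz - b.theoretical_mz)
                        <= 5e-6 * a.theoretical_mz
                    )
                    if close_rt and close_mz:
                        warnings.warn(
                            f"{sample}: {a.name} and {b.name} overlap in RT and "
                            "m/z; fixture is ambiguous",
                            stacklevel=3,
                        )


def groundwater_scenario(seed: int = 7, area: float = 5e5) -> Scenario:
    """The bundled reference scenario: 11 PFAS over three groundwater samples.

    Each catalog compound is injected into its samples with its cataloged
    retention time and signed ppm error.  Fragment mass offsets use the
    published measured product-ion m/z where one exists, otherwise a seeded
    draw within +/-2 mDa.  Every sample also receives one decoy peak per
    screening failure mode, targeting the decoy entries of the suspect list.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xD0]))
    decoy_mz = {
        name: mz_deprotonated(monoisotopic_mass(parse_formula(f)))
        for name, _cls, f in DECOY_SUSPECTS
    }
    samples: Dict[str, SampleSpec] = {}
    for sample in SAMPLES:
        compounds = []
        for c in COMPOUNDS:
            if sample not in c.samples:
                continue
            frags = []
            for formula, observed in c.fragments.items():
                theo = fragment_mz(formula)
                if observed is not None:
                    offset = (observed - theo) * 1e3
                else:
                    offset = float(rng.uniform(-2.0, 2.0))
                frags.append((formula, offset))
            compounds.append(
                InjectedCompound(
                    name=c.name,
                    theoretical_mz=c.theoretical_mz,
                    rt=c.rt,
                    area=area,
                    ppm=c.samples[sample],
                    fragments=tuple(frags),
                )
            )
        decoys = (
            InjectedDecoy("sub_area", "PFHpS", decoy_mz["PFHpS"], rt=5.2, area=3e4),
            InjectedDecoy(
                "sub_snr", "PFDS", decoy_mz["PFDS"], rt=7.0, area=1.6e5,
                baseline_mean=1.5e5, baseline_sd=7e4,
            ),
            InjectedDecoy(
                "blank_contaminant", "PFOA", decoy_mz["PFOA"], rt=3.0, area=8e5,
                in_blank=True,
            ),
            InjectedDecoy(
                "single_replicate", "PFNA", decoy_mz["PFNA"], rt=6.2, area=6e5,
                replicates=(1,),
            ),
            InjectedDecoy("off_ppm", "PFHxA", decoy_mz["PFHxA"], rt=4.5, area=7e5, ppm=8.0),
        )
        samples[sample] = SampleSpec(compounds=tuple(compounds), decoys=decoys)
    return Scenario(samples=samples, seed=seed)


# ---------------------------------------------------------------------------
# run synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Channel:
    measured_mz: float
    rt: float
    height: float  # Gaussian peak height, 0 for baseline-only channels
    baseline_mean: float
    baseline_sd: float


def _run_rng(scenario: Scenario, sample_id: str, replicate: int, role: str):
    tag = zlib.crc32(f"{role}:{sample_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([scenario.seed & 0x7FFFFFFF, tag, replicate])
    )


def _peak_height(area: float, sigma: float) -> float:
    return area / (sigma * np.sqrt(2.0 * np.pi))


def _merge_sorted(mz: np.ndarray, inten: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if mz.size > 1:
        dup = np.diff(mz) <= 0
        if dup.any():  # merge exact collisions to keep strict ordering
            keep = np.concatenate(([True], ~dup))
            idx = np.cumsum(keep) - 1
            merged = np.zeros(keep.sum())
            np.add.at(merged, idx, inten)
            mz, inten = mz[keep], merged
    return mz, inten


def _ms1_scan(
    rng, t: float, channels: Sequence[_Channel], scenario: Scenario
) -> CentroidSpectrum:
    n = scenario.noise_centroids_per_scan
    mz = list(rng.uniform(70.0, 1040.0, n))
    inten = list(rng.exponential(scenario.noise_intensity_mean, n))
    sigma = scenario.peak_sigma
    for ch in channels:
        level = max(float(rng.normal(ch.baseline_mean, ch.baseline_sd)), 0.0)
        if ch.height > 0 and abs(t - ch.rt) < 5 * sigma:
            level += ch.height * np.exp(-0.5 * ((t - ch.rt) / sigma) ** 2)
        if level <= 0:
            continue
        jitter = rng.normal(0.0, scenario.mz_jitter_ppm) * 1e-6
        mz.append(ch.measured_mz * (1.0 + jitter))
        inten.append(level)
    mzs, ints = _merge_sorted(np.asarray(mz), np.asarray(inten))
    return CentroidSpectrum(ms_level=1, rt=t, mz=mzs, intensity=ints)


def _ms2_spectrum(
    rng, t: float, compound: InjectedCompound, scenario: Scenario
) -> CentroidSpectrum:
    mz = []
    inten = []
    for i, (formula, offset_mda) in enumerate(compound.fragments):
        mz.append(fragment_mz(formula) + offset_mda * 1e-3)
        inten.append(1e5 * 0.8**i)
    k = scenario.ms2_noise_peaks
    mz.extend(rng.uniform(50.0, max(compound.measured_mz - 5.0, 60.0), k))
    inten.extend(rng.exponential(300.0, k))
    mzs, ints = _merge_sorted(np.asarray(mz), np.asarray(inten))
    return CentroidSpectrum(
        ms_level=2,
        rt=t,
        mz=mzs,
        intensity=ints,
        precursor_mz=compound.measured_mz,
        isolation_halfwidth=scenario.isolation_halfwidth,
        collision_energies=scenario.collision_energies,
    )


def _build_run(
    scenario: Scenario,
    sample_id: str,
    role: str,
    replicate: int,
    channels: Sequence[_Channel],
    ms2_compounds: Sequence[InjectedCompound],
) -> Run:
    rng = _run_rng(scenario, sample_id, replicate, role)
    lo, hi = scenario.rt_span
    grid = np.arange(lo + scenario.scan_spacing, hi, scenario.scan_spacing)
    timeline: List[Tuple[float, int, CentroidSpectrum]] = []
    for t in grid:
        timeline.append((t, 0, _ms1_scan(rng, float(t), channels, scenario)))
    for compound in ms2_compounds:
        for event in range(scenario.ms2_events_per_peak):
            t = compound.rt + scenario.scan_spacing * (event + 0.35)
            timeline.append((t, 1, _ms2_spectrum(rng, t, compound, scenario)))
    timeline.sort(key=lambda item: (item[0], item[1]))
    return Run(
        spectra=[s for _, _, s in timeline],
        sample_id=sample_id,
        role=role,
        replicate=replicate,
    )


def build_runs(scenario: Scenario) -> List[Run]:
    """Realize the scenario as in-memory runs (samples in duplicate + blanks)."""
    runs: List[Run] = []
    sigma = scenario.peak_sigma
    blank_channels: List[_Channel] = []
    for sample_id in sorted(scenario.samples):
        spec = scenario.samples[sample_id]
        for d in spec.decoys:
            if d.in_blank:
                blank_channels.append(
                    _Channel(
                        measured_mz=d.measured_mz,
                        rt=d.rt,
                        height=_peak_height(d.area, sigma),
                        baseline_mean=d.baseline_mean or scenario.baseline_mean,
                        baseline_sd=d.baseline_sd or scenario.baseline_sd,
                    )
                )
        for replicate in (1, 2):
            channels = [
                _Channel(
                    measured_mz=c.measured_mz,
                    rt=c.rt,
                    height=_peak_height(c.area, sigma),
                    baseline_mean=scenario.baseline_mean,
                    baseline_sd=scenario.baseline_sd,
                )
                for c in spec.compounds
            ]
            channels += [
                _Channel(
                    measured_mz=d.measured_mz,
                    rt=d.rt,
                    height=_peak_height(d.area, sigma),
                    baseline_mean=d.baseline_mean or scenario.baseline_mean,
                    baseline_sd=d.baseline_sd or scenario.baseline_sd,
                )
                for d in spec.decoys
                if replicate in d.replicates
            ]
            channels.sort(key=lambda ch: ch.measured_mz)
            runs.append(
                _build_run(
                    scenario, sample_id, "sample", replicate, channels, spec.compounds
                )
            )
    blank_channels.sort(key=lambda ch: ch.measured_mz)
    for b in range(1, scenario.n_blanks + 1):
        runs.append(
            _build_run(scenario, "Blank", "blank", b, blank_channels, ())
        )
    return runs


def simulate_runs(scenario: Scenario, outdir) -> str:
    """Write the scenario's runs as mzML plus a run manifest and libraries.

    Returns the manifest path.  File contents are byte-identical across
    invocations with the same scenario.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs: List[RunSpec] = []
    for run in build_runs(scenario):
        fname = f"{run.sample_id}_r{run.replicate}.mzml"
        write_mzml(outdir / fname, run.spectra, run_id=f"{run.sample_id}/{run.replicate}")
        specs.append(
            RunSpec(
                sample_id=run.sample_id,
                role=run.role,
                replicate=run.replicate,
                path=fname,
            )
        )
    manifest = outdir / "manifest.csv"
    write_manifest(manifest, specs)
    write_libraries(outdir)
    return str(manifest)
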