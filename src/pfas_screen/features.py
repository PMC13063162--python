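"""Chromatographic peak detection and threshold filtering.

A :class:`Feature` is one integrated chromatographic peak in one run's
extracted ion chromatogram: intensity-weighted mean centroid m/z, apex RT,
trapezoidal area (counts x minutes), apex height, and a signal-to-noise
ratio.  Screening keeps only features with area >= 100,000 and S/N >= 50
(both inclusive), the thresholds typical of Orbitrap suspect-screening
feature selection.

S/N is apex height divided by a robust baseline-noise estimate: 1.4826 times
the median absolute deviation from the EIC median, computed over the points
below the median so chromatographic peaks do not inflate the estimate.  For
pure Gaussian baseline noise this recovers the noise standard deviation; the
estimate is floored at 1 count so S/N stays finite on empty channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .msio import EIC, Run, extract_eic

__all__ = [
    "Feature",
    "RawPeak",
    "estimate_noise",
    "detect_peaks",
    "build_features",
    "filter_features",
]

NOISE_FLOOR = 1.0


@dataclass(frozen=True)
class Feature:
    """A detected chromatographic peak with its sample identity."""

    mz: float  # intensity-weighted mean centroid m/z over the peak (Th)
    rt_apex: float  # minutes
    area: float  # counts x minutes
    height: float  # counts
    snr: float
    sample_id: str
    replicate: int
    rt_left: float = 0.0  # peak boundary, minutes
    rt_right: float = 0.0
    target_mz: float = 0.0  # EIC target that produced the feature


@dataclass(frozen=True)
class RawPeak:
    apex_index: int
    left_index: int
    right_index: int
    rt_apex: float
    height: float
    area: float


def estimate_noise(eic: EIC) -> float:
    """Robust baseline noise of an EIC (counts), floored at 1.

    Deviations from the EIC median are taken over the points strictly below
    the median (scaled by 1.4826), so an isolated peak or spike contributes
    nothing: the estimate reflects the baseline.
    """
    y = eic.intensity
    if y.size < 8:
        raise ValueError(f"EIC has {y.size} points; need >= 8 to estimate noise")
    med = np.median(y)
    below = y[y < med]
    if below.size == 0:
        return NOISE_FLOOR
    noise = 1.4826 * np.median(med - below)
    return max(float(noise), NOISE_FLOOR)


def detect_peaks(eic: EIC, noise: float) -> List[RawPeak]:
    """Local-maximum peak picking with baseline-return boundaries.

    A peak is a local maximum with height >= 3 x noise.  Boundaries extend
    down each flank while intensity is non-increasing, stopping at a local
    minimum or once the trace returns to baseline (<= noise).  Area is the
    trapezoid over RT between the boundaries.
    """
    if noise <= 0:
        raise ValueError("noise must be positive")
    y = eic.intensity
    rt = eic.rt
    n = y.size
    peaks: List[RawPeak] = []
    for i in range(n):
        left_ok = i == 0 or y[i] > y[i - 1]
        right_ok = i == n - 1 or y[i] >= y[i + 1]
        if not (left_ok and right_ok) or y[i] < 3.0 * noise:
            continue
        lo = i
        while lo > 0 and y[lo] > noise and y[lo - 1] <= y[lo]:
            lo -= 1
        hi = i
        while hi < n - 1 and y[hi] > noise and y[hi + 1] <= y[hi]:
            hi += 1
        area = float(np.trapezoid(y[lo : hi + 1], rt[lo : hi + 1])) if hi > lo else 0.0
        peaks.append(
            RawPeak(
                apex_index=i,
                left_index=lo,
                right_index=hi,
                rt_apex=float(rt[i]),
                height=float(y[i]),
                area=area,
            )
        )
    return peaks


def _weighted_mz(eic: EIC, peak: RawPeak) -> float:
    sl = slice(peak.left_index, peak.right_index + 1)
    total = eic.intensity[sl].sum()
    if total <= 0:
        return eic.target_mz
    return float(eic.mz_weight[sl].sum() / total)


def build_features(
    run: Run,
    targets: Sequence[float],
    tol_ppm: float = 5.0,
) -> List[Feature]:
    """Extract EICs at the target m/z values and integrate their peaks."""
    features: List[Feature] = []
    for target in targets:
        eic = extract_eic(run, target, tol_ppm)
        if eic.intensity.size < 8:
            continue
        noise = estimate_noise(eic)
        for peak in detect_peaks(eic, noise):
            if peak.area <= 0 or peak.height <= 0:
                continue
            features.append(
                Feature(
                    mz=_weighted_mz(eic, peak),
                    rt_apex=peak.rt_apex,
                    area=peak.area,
                    height=peak.height,
                    snr=peak.height / noise,
                    sample_id=run.sample_id,
                    replicate=run.replicate,
                    rt_left=float(eic.rt[peak.left_index]),
                    rt_right=float(eic.rt[peak.right_index]),
                    target_mz=target,
                )
            )
    return features


def filter_features(
    features: Iterable[Feature],
    min_area: float = 100_000.0,
    min_snr: float = 50.0,
) -> List[Feature]:
    """Keep features with area >= min_area AND S/N >= min_snr (inclusive)."""
    if min_area < 0 or min_snr < 0:
        raise ValueError("thresholds must be non-negative")
    return [f for f in features if f.area >= min_area and f.snr >= min_snr]
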