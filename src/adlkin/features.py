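"""The nine kinematic parameters of a preprocessed magnitude signal.

The parameters are grouped by what they intend to measure:

========== ======================= =====================================
group      parameter               definition
========== ======================= =====================================
activity   TD (s)                  trial duration
activity   RA (–)                  fraction of samples above 0.2 m/s²
agility    STD (m/s²)              SD of acceleration-peak heights
smoothness PPS (1/s)               acceleration peaks per second
smoothness RATIO (–)               share of peaks with prominence ≥ 0.2
energy     SUM (m²/s⁵)             Σ a² / TD
energy     APS (m/s³)              Σ a / TD
intensity  MPA (m/s²)              mean peak height
intensity  MAX95 (m/s²)            95th percentile of peak heights
========== ======================= =====================================

Peaks are *all* strict local maxima of the smoothed magnitude — no
height floor — because RATIO relates distinct movements to all
movements including noise.  Quantities that are undefined on a given
signal (e.g. STD with fewer than two peaks) are reported as NaN, never
as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .errors import ConfigurationError
from .preprocess import MagnitudeSignal

PARAMETERS = ("TD", "RA", "STD", "PPS", "RATIO", "SUM", "APS", "MPA", "MAX95")

GROUP_TAGS = {
    "activity": ("TD", "RA"),
    "agility": ("STD",),
    "smoothness": ("PPS", "RATIO"),
    "energy": ("SUM", "APS"),
    "intensity": ("MPA", "MAX95"),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds of the peak-based parameters.

    ``activity_threshold`` (m/s²) separates movement from inactivity for
    RA (strict ``>``); ``prominence_threshold`` (m/s²) separates distinct
    movements from noise peaks for RATIO (inclusive ``>=``).
    """

    activity_threshold: float = 0.2
    prominence_threshold: float = 0.2
    percentile: float = 95.0

    def __post_init__(self) -> None:
        if self.activity_threshold <= 0 or self.prominence_threshold <= 0:
            raise ConfigurationError("thresholds must be > 0")
        if not 0 < self.percentile < 100:
            raise ConfigurationError("percentile must be in (0, 100)")


@dataclass
class PeakSet:
    """Local maxima of a magnitude signal.

    ``indices`` are sample positions (plateaus are represented by the
    first sample of the plateau), ``heights`` the signal values there,
    ``prominences`` the topographic prominence of each peak with the
    series edges acting as terrain boundaries.
    """

    indices: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return self.indices.size


def detect_peaks(sig: MagnitudeSignal) -> PeakSet:
    """Find every strict local maximum and its prominence."""
    a = np.asarray(sig.a, dtype=float)
    if a.size < 3:
        warnings.warn("signal shorter than 3 samples: no peaks defined", stacklevel=2)
        return PeakSet(np.empty(0, int), np.empty(0), np.empty(0))
    peaks, props = find_peaks(a, plateau_size=1)
    indices = props["left_edges"].astype(int)
    prom = peak_prominences(a, peaks)[0]
    return PeakSet(indices=indices, heights=a[indices], prominences=prom)


def trial_duration(sig: MagnitudeSignal) -> float:
    """TD: time to execute the task, seconds."""
    if sig.a.size == 0:
        warnings.warn("empty signal: trial duration is 0", stacklevel=2)
        return 0.0
    return sig.a.size / sig.sample_rate


def relative_activity(sig: MagnitudeSignal, cfg: FeatureConfig | None = None) -> float:
    """RA: fraction of samples strictly above the activity threshold."""
    cfg = cfg or FeatureConfig()
    return float(np.mean(sig.a > cfg.activity_threshold))


def peak_std(peaks: PeakSet) -> float:
    """STD: sample standard deviation (n−1) of peak heights; NaN if < 2 peaks."""
    if len(peaks) < 2:
        return float("nan")
    return float(np.std(peaks.heights, ddof=1))


def peaks_per_second(peaks: PeakSet, td: float) -> float:
    """PPS: number of peaks divided by trial duration."""
    if td <= 0:
        raise ValueError("trial duration must be > 0")
    return len(peaks) / td


def peak_ratio(peaks: PeakSet, cfg: FeatureConfig | None = None) -> float:
    """RATIO: share of peaks with prominence ≥ threshold; NaN without peaks."""
    cfg = cfg or FeatureConfig()
    if len(peaks) == 0:
        return float("nan")
    return float(np.mean(peaks.prominences >= cfg.prominence_threshold))


def weighted_sum_acc(sig: MagnitudeSignal) -> float:
    """SUM: Σ a² over samples, divided by trial duration (m²/s⁵).

    Equivalent to mean(a²) × sample_rate; squaring down-weights noise and
    small movements relative to energetic ones.
    """
    td = trial_duration(sig)
    if td <= 0:
        return 0.0
    return float(np.sum(np.square(sig.a)) / td)


def acc_per_second(sig: MagnitudeSignal) -> float:
    """APS: Σ a over samples, divided by trial duration (m/s³)."""
    td = trial_duration(sig)
    if td <= 0:
        return 0.0
    return float(np.sum(sig.a) / td)


def mean_peak_acc(peaks: PeakSet) -> float:
    """MPA: arithmetic mean of peak heights; NaN without peaks."""
    if len(peaks) == 0:
        return float("nan")
    return float(np.mean(peaks.heights))


def max95(peaks: PeakSet, cfg: FeatureConfig | None = None) -> float:
    """MAX95: percentile of peak heights, linear interpolation at (n−1)p."""
    cfg = cfg or FeatureConfig()
    if len(peaks) == 0:
        return float("nan")
    return float(np.percentile(peaks.heights, cfg.percentile))


@dataclass
class KinematicProfile:
    """All nine parameters of one recording; NaN marks undefined values."""

    TD: float
    RA: float
    STD: float
    PPS: float
    RATIO: float
    SUM: float
    APS: float
    MPA: float
    MAX95: float

    group_tags = GROUP_TAGS

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def extract_profile(sig: MagnitudeSignal, cfg: FeatureConfig | None = None) -> KinematicProfile:
    """Compute all nine parameters from one peak-detection pass."""
    cfg = cfg or FeatureConfig()
    td = trial_duration(sig)
    peaks = detect_peaks(sig) if sig.a.size >= 3 else PeakSet(np.empty(0, int), np.empty(0), np.empty(0))
    return KinematicProfile(
        TD=td,
        RA=relative_activity(sig, cfg),
        STD=peak_std(peaks),
        PPS=peaks_per_second(peaks, td) if td > 0 else 0.0,
        RATIO=peak_ratio(peaks, cfg),
        SUM=weighted_sum_acc(sig),
        APS=acc_per_second(sig),
        MPA=mean_peak_acc(peaks),
        MAX95=max95(peaks, cfg),
    )
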