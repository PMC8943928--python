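"""Raw wrist acceleration to a smoothed, gravity-free magnitude signal.

The processing chain mirrors the standard smartwatch-accelerometry recipe
for manual task analysis:

1. per-sample Euclidean norm of the tri-axial vector (m/s²),
2. subtraction of standard gravity as a constant, with rectification
   (absolute value) so that the result is a non-negative deviation from
   the resting magnitude,
3. loess smoothing — locally weighted quadratic regression with tricube
   weights over a fixed 420 ms span.

Every downstream kinematic parameter is defined on the resulting
:class:`MagnitudeSignal`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: Standard gravity in m/s², subtracted as a constant from the magnitude.
STANDARD_GRAVITY = 9.81


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the magnitude pipeline.

    Attributes
    ----------
    gravity:
        Constant subtracted from the magnitude, m/s².  The resting
        magnitude of an accelerometer is the local gravity; no orientation
        estimate is attempted, so the constant is the whole model.
    smooth_window:
        Loess span in seconds (default 0.420 s).
    loess_degree:
        Degree of the local polynomial (default 2, classic loess).
    rectify:
        Take the absolute value after gravity subtraction (default True).
    """

    gravity: float = STANDARD_GRAVITY
    smooth_window: float = 0.420
    loess_degree: int = 2
    rectify: bool = True

    def __post_init__(self) -> None:
        if self.smooth_window <= 0:
            raise ConfigurationError("smooth_window must be > 0")
        if self.gravity < 0:
            raise ConfigurationError("gravity must be >= 0")
        if self.loess_degree < 0:
            raise ConfigurationError("loess_degree must be >= 0")


@dataclass
class RawRecording:
    """One tri-axial recording of a participant performing one task."""

    participant_id: str
    task: str
    sample_rate: float
    t: np.ndarray
    axyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.axyz = np.asarray(self.axyz, dtype=float)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        if self.axyz.ndim != 2 or self.axyz.shape[1] != 3:
            raise ValidationError("axyz must have shape (n, 3)")
        if self.t.shape[0] != self.axyz.shape[0]:
            raise ValidationError("t and axyz must have the same length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.axyz.shape[0]


@dataclass
class MagnitudeSignal:
    """Preprocessed scalar acceleration magnitude, m/s², non-negative."""

    sample_rate: float
    a: np.ndarray
    provenance: PreprocessConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n_samples / sample_rate)."""
        return self.a.size / self.sample_rate


def magnitude(raw: RawRecording) -> np.ndarray:
    """Per-sample Euclidean norm of the tri-axial acceleration vector."""
    bad = ~np.isfinite(raw.axyz)
    if bad.any():
        idx = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise ValidationError(f"non-finite acceleration sample at index {idx}")
    return np.linalg.norm(raw.axyz, axis=1)


def remove_gravity(mag: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Subtract gravity as a constant; rectify unless disabled."""
    cfg = cfg or PreprocessConfig()
    out = np.asarray(mag, dtype=float) - cfg.gravity
    return np.abs(out) if cfg.rectify else out


def _tricube(u: np.ndarray) -> np.ndarray:
    w = 1.0 - np.abs(u) ** 3
    return np.clip(w, 0.0, None) ** 3


def _loess_span(window: float, sample_rate: float, degree: int) -> int:
    span = int(round(window * sample_rate))
    if span % 2 == 0:
        span += 1  # centered windows need an odd span
    if span < degree + 2:
        raise ConfigurationError(
            f"smoothing window of {span} samples cannot support a degree-{degree} fit"
        )
    return span


def smooth_loess(
    sig: np.ndarray,
    sample_rate: float,
    window: float = 0.420,
    degree: int = 2,
) -> np.ndarray:
    """Loess-smooth a series: local polynomial fit with tricube weights.

    The span is ``round(window * sample_rate)`` samples, rounded to the
    nearest odd count so windows are centered.  At the boundaries the
    window is truncated (no padding).  Interior points share identical
    regressor offsets and weights, so the smoother reduces to a single
    fixed convolution kernel there; boundary points fall back to explicit
    weighted least squares on the truncated window.
    """
    y = np.asarray(sig, dtype=float)
    n = y.size
    if n == 0:
        return y.copy()
    span = _loess_span(window, sample_rate, degree)
    h = (span - 1) // 2

    out = np.empty(n)
    if n >= span:
        x = np.arange(-h, h + 1, dtype=float)
        w = _tricube(x / (h + 1))
        A = np.vander(x, degree + 1, increasing=True)
        # row of the hat matrix for the window center: e0ᵀ (AᵀWA)⁻¹ AᵀW
        kernel = np.linalg.solve(A.T * w @ A, A.T * w)[0]
        out[h : n - h] = np.correlate(y, kernel, mode="valid")
        edge_idx = list(range(h)) + list(range(n - h, n))
    else:
        edge_idx = list(range(n))

    for i in edge_idx:
        lo, hi = max(0, i - h), min(n, i + h + 1)
        x = np.arange(lo, hi, dtype=float) - i
        w = _tricube(x / (h + 1))
        deg = min(degree, hi - lo - 1)
        A = np.vander(x, deg + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], y[lo:hi] * sw, rcond=None)
        out[i] = coef[0]
    return out


def _resample_if_irregular(raw: RawRecording) -> RawRecording:
    """Linear-interpolate onto the nominal grid when timestamps drift."""
    if raw.n_samples < 3:
        return raw
    dt = np.diff(raw.t)
    nominal = 1.0 / raw.sample_rate
    dev = np.abs(dt - nominal) / nominal
    if np.mean(dev > 0.10) <= 0.01:
        return raw
    warnings.warn(
        f"recording {raw.participant_id}/{raw.task}: >1% of sample intervals "
        "deviate by >10% from nominal; resampling by linear interpolation",
        stacklevel=3,
    )
    t_new = raw.t[0] + np.arange(int(np.floor((raw.t[-1] - raw.t[0]) * raw.sample_rate)) + 1) * nominal
    axyz = np.column_stack([np.interp(t_new, raw.t, raw.axyz[:, k]) for k in range(3)])
    return RawRecording(raw.participant_id, raw.task, raw.sample_rate, t_new, axyz)


def preprocess(raw: RawRecording, cfg: PreprocessConfig | None = None) -> MagnitudeSignal:
    """Full chain: magnitude → gravity removal → loess smoothing.

    Negative values that the smoother introduces near sharp transitions
    are clipped at zero, keeping the output a valid magnitude.
    """
    cfg = cfg or PreprocessConfig()
    raw = _resample_if_irregular(raw)
    m = magnitude(raw)
    r = remove_gravity(m, cfg)
    s = smooth_loess(r, raw.sample_rate, cfg.smooth_window, cfg.loess_degree)
    if cfg.rectify:
        s = np.clip(s, 0.0, None)
    return MagnitudeSignal(sample_rate=raw.sample_rate, a=s, provenance=cfg)


def read_recording_csv(
    path, participant_id: str = "", task: str = "", sample_rate: float = 100.0
) -> RawRecording:
    """Read a ``t,ax,ay,az`` CSV (header optional) into a RawRecording."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if set(cols) >= {"t", "ax", "ay", "az"}:
        df.columns = cols
    else:  # headerless file: first row was data
        df = pd.read_csv(path, header=None, names=["t", "ax", "ay", "az"])
    t = df["t"].to_numpy(float)
    axyz = df[["ax", "ay", "az"]].to_numpy(float)
    if t.size > 1:
        sample_rate = (t.size - 1) / (t[-1] - t[0])
    return RawRecording(participant_id, task, float(sample_rate), t, axyz)


def write_preprocessed_csv(sig: MagnitudeSignal, path) -> None:
    """Write a preprocessed signal as a ``t,a`` CSV."""
    t = np.arange(sig.a.size) / sig.sample_rate
    pd.DataFrame({"t": t, "a": sig.a}).to_csv(path, index=False)
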