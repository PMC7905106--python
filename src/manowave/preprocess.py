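"""Artifact reduction and log transformation of raw pressure recordings.

A manometry recording is a channels x time matrix of pressures (mmHg).
Before spectral decomposition three steps are applied, in this order:

1. running-median baseline removal per channel,
2. detection and exclusion of synchronous pressure increases -- rises that
   occur across *all* channels at once (typically strain/cough artifacts;
   waves spanning only a subset of channels are left untouched),
3. clamping of pressures below a floor (1 mmHg) followed by the natural
   logarithm, so high-amplitude events do not overpower low-amplitude
   oscillations.

Samples flagged as synchronous increases are excluded from all downstream
time-averages; for the wavelet transform itself (which needs a gapless
signal) the flagged samples are filled by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "RecordingMeta",
    "PressureRecording",
    "SyncDetectorConfig",
    "clamp_log",
    "remove_baseline",
    "remove_synchronous_increases",
    "preprocess_recording",
    "Preprocessor",
]

GROUPS = ("healthy", "patient")
REGIONS = ("descending", "sigmoid")
MEALS = ("preprandial", "postprandial")


@dataclass
class RecordingMeta:
    """Experimental labels attached to one recording."""

    subject: str = "s0"
    group: str = "healthy"
    region: str = "descending"
    meal: str = "preprandial"
    nchan: int = 0

    def as_dict(self) -> dict:
        return {"subject": self.subject, "group": self.group,
                "region": self.region, "meal": self.meal, "nchan": self.nchan}


@dataclass
class PressureRecording:
    """Channels x time pressure matrix with sampling metadata.

    Parameters
    ----------
    pressures : ndarray, shape (n_channels, n_time)
        Pressures in mmHg; channels ordered proximal to distal.
    fs : float
        Sampling rate in Hz.
    spacing : float
        Inter-sensor distance in cm.
    meta : RecordingMeta
        Subject/group/region/meal labels and channel count.
    mask : ndarray of bool, shape (n_time,), optional
        True where a sample is excluded from time averages.
    """

    pressures: np.ndarray
    fs: float
    spacing: float = 1.0
    meta: RecordingMeta = field(default_factory=RecordingMeta)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.pressures.ndim != 2:
            raise ValueError("pressures must be a 2D channels x time matrix")
        if self.pressures.shape[0] < 2 or self.pressures.shape[1] < 2:
            raise ValueError("need at least 2 channels and 2 time samples")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if self.spacing <= 0:
            raise ValueError("sensor spacing must be positive")
        if self.meta.nchan == 0:
            self.meta.nchan = self.pressures.shape[0]
        elif self.meta.nchan != self.pressures.shape[0]:
            raise ValueError(
                f"meta.nchan={self.meta.nchan} does not match channel "
                f"dimension {self.pressures.shape[0]}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.pressures.shape[1],):
                raise ValueError("mask length must equal the time axis")

    @property
    def n_channels(self) -> int:
        return self.pressures.shape[0]

    @property
    def n_time(self) -> int:
        return self.pressures.shape[1]

    @property
    def duration(self) -> float:
        return self.n_time / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_time) / self.fs


@dataclass
class SyncDetectorConfig:
    """All-channel rise-rate detector for synchronous pressure increases.

    A sample t is flagged when every channel shows a pressure rise of at
    least ``min_rise`` mmHg over the preceding ``rise_window_s`` seconds.
    """

    min_rise: float = 5.0
    rise_window_s: float = 2.0


def clamp_log(rec: PressureRecording, floor: float = 1.0) -> PressureRecording:
    """Clamp pressures below ``floor`` (mmHg) to the floor, then take ln."""
    if floor <= 0:
        raise ValueError("clamp floor must be positive")
    p = rec.pressures
    if not np.all(np.isfinite(p)):
        ch, t = np.argwhere(~np.isfinite(p))[0]
        raise ValueError(f"non-finite pressure at channel {ch}, sample {t}")
    return replace(rec, pressures=np.log(np.maximum(p, floor)))


def remove_baseline(rec: PressureRecording,
                    window_s: float = 120.0) -> PressureRecording:
    """Subtract a per-channel running-median baseline estimate.

    The window is ``window_s`` seconds (at least 3 samples).  A constant
    offset or slow drift is removed; oscillations faster than the window
    pass through essentially unchanged.
    """
    n = int(round(window_s * rec.fs))
    if n < 3:
        raise ValueError(
            f"baseline window of {window_s}s is {n} samples at fs={rec.fs}; "
            "need at least 3")
    if n % 2 == 0:
        n += 1
    baseline = median_filter(rec.pressures, size=(1, n), mode="nearest")
    return replace(rec, pressures=rec.pressures - baseline)


def _rise(p: np.ndarray, w: int) -> np.ndarray:
    """Pressure rise over the trailing w samples (edge samples compare
    against the first sample)."""
    shifted = np.empty_like(p)
    shifted[:, w:] = p[:, :-w]
    shifted[:, :w] = p[:, :1]
    return p - shifted


def remove_synchronous_increases(
    rec: PressureRecording,
    detector: SyncDetectorConfig | None = None,
) -> tuple[PressureRecording, np.ndarray]:
    """Flag samples where *all* channels rise simultaneously.

    Returns the recording with flagged samples linearly interpolated
    per channel (unflagged samples are bit-identical to the input) and the
    boolean exclusion mask.  Pressure waves spanning only a subset of
    channels are not affected.
    """
    detector = detector or SyncDetectorConfig()
    w = max(1, int(round(detector.rise_window_s * rec.fs)))
    rise = _rise(rec.pressures, w)
    mask = np.all(rise >= detector.min_rise, axis=0)
    out = rec.pressures
    if mask.any():
        out = out.copy()
        t = np.arange(rec.n_time)
        keep = ~mask
        if not keep.any():
            raise ValueError("synchronous-increase detector flagged every "
                             "sample; nothing left to analyze")
        for c in range(rec.n_channels):
            out[c, mask] = np.interp(t[mask], t[keep], out[c, keep])
    combined = mask if rec.mask is None else (mask | rec.mask)
    return replace(rec, pressures=out, mask=combined), mask


def preprocess_recording(
    rec: PressureRecording,
    window_s: float = 120.0,
    detector: SyncDetectorConfig | None = None,
    floor: float = 1.0,
    sync_removal: bool = True,
    baseline_removal: bool = True,
) -> PressureRecording:
    """Full pipeline: baseline -> synchronous removal -> clamp + log.

    Note the clamp floor applies to the baseline-subtracted pressures, so
    only excursions above the local baseline survive the log transform.
    """
    if baseline_removal:
        rec = remove_baseline(rec, window_s=window_s)
    if sync_removal:
        rec, _ = remove_synchronous_increases(rec, detector)
    return clamp_log(rec, floor=floor)


class Preprocessor:
    """sklearn-style transformer running the preprocessing pipeline.

    Parameters mirror :func:`preprocess_recording`.  ``transform`` maps a
    :class:`PressureRecording` (or list of recordings) to its preprocessed
    counterpart; the exclusion mask travels on the returned recording.
    """

    def __init__(self, window_s: float = 120.0, min_rise: float = 5.0,
                 rise_window_s: float = 2.0, floor: float = 1.0,
                 sync_removal: bool = True, baseline_removal: bool = True):
        self.window_s = window_s
        self.min_rise = min_rise
        self.rise_window_s = rise_window_s
        self.floor = floor
        self.sync_removal = sync_removal
        self.baseline_removal = baseline_removal

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("window_s", "min_rise", "rise_window_s", "floor",
                 "sync_removal", "baseline_removal")}

    def set_params(self, **params) -> "Preprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "Preprocessor":
        return self  # stateless

    def transform(self, X):
        detector = SyncDetectorConfig(self.min_rise, self.rise_window_s)
        one = isinstance(X, PressureRecording)
        recs = [X] if one else list(X)
        out = [preprocess_recording(
            r, window_s=self.window_s, detector=detector, floor=self.floor,
            sync_removal=self.sync_removal,
            baseline_removal=self.baseline_removal) for r in recs]
        return out[0] if one else out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
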