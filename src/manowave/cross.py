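"""Cross-wavelet transforms and frequency x phase-difference histograms.

For two nearby sensors a (proximal) and b (distal), the cross-wavelet
transform ``v_ab = v_a * conj(v_b)`` has phase equal to the phase difference
between the channels, which encodes propagation: its sign gives the
direction (positive = antegrade under the proximal-first convention) and
its magnitude, via ``u = d * 2*pi*f / phi``, the apparent velocity for
sensor separation d (cm).  Phase-locked (synchronous) activity sits at
phi = 0, which maps to pace 1/u = 0 -- preferred over an infinite velocity.

Binning |v_ab(t, f)| by the phase difference at each frequency yields the
2D histogram response: the per-bin *mean* amplitude (bin-count normalized),
with empty bins floored before the log so the response stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PressureRecording
from .wavelet import FrequencyGrid, WaveletSpectrum, SynchrosqueezedCWT

__all__ = [
    "PhaseGrid",
    "Spectrum2D",
    "cross_wavelet",
    "phase_histogram",
    "phase_to_velocity",
    "velocity_to_phase",
    "pace_of",
    "CrossSpectrum",
]


@dataclass
class PhaseGrid:
    """M equal-width phase-difference bins covering (-pi, pi].

    Membership is half-open [edge, next_edge) with +pi wrapped into the
    last bin, keeping the circle covered exactly once.
    """

    n: int = 18

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 phase bins")
        self.edges = np.linspace(-np.pi, np.pi, self.n + 1)
        self.centers = 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def width(self) -> float:
        return 2.0 * np.pi / self.n

    def bin_index(self, phi) -> np.ndarray:
        phi = np.asarray(phi, float)
        idx = np.floor((phi + np.pi) / self.width).astype(int)
        return np.clip(idx, 0, self.n - 1)  # +pi lands in the last bin


@dataclass
class Spectrum2D:
    """Log binned cross-power over frequency x phase; one observation.

    ``power`` is the pre-log histogram and ``counts`` the per-bin sample
    counts |T_phi(f)|, kept so that the partition identity
    sum_phi counts * power == sum_t |v_ab| can be audited per frequency.
    """

    y: np.ndarray                      # (K, M) log response
    fgrid: FrequencyGrid
    pgrid: PhaseGrid
    power: np.ndarray | None = None    # (K, M) mean |v_ab| per bin
    counts: np.ndarray | None = None   # (K, M) samples per bin
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        if self.y.shape != (self.fgrid.n_bins, self.pgrid.n):
            raise ValueError("y must be (n_freq_bins, n_phase_bins)")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("2D spectrum contains non-finite values")


def cross_wavelet(v_a: WaveletSpectrum, v_b: WaveletSpectrum) -> np.ndarray:
    """Complex-conjugated product of two synchrosqueezed spectra.

    The result's angle is the phase of a minus the phase of b.
    """
    if v_a.v.shape != v_b.v.shape:
        raise ValueError("spectra have different shapes")
    if v_a.fs != v_b.fs:
        raise ValueError("spectra have different sampling rates")
    if not np.allclose(v_a.grid.centers, v_b.grid.centers):
        raise ValueError("spectra are on different frequency grids")
    return v_a.v * np.conj(v_b.v)


def phase_histogram(v_ab, pgrid: PhaseGrid, fgrid: FrequencyGrid,
                    mask: np.ndarray | None = None,
                    floor_rel: float = 1e-12,
                    weight: str = "amplitude",
                    meta: dict | None = None) -> Spectrum2D:
    """Frequency x phase histogram of cross-wavelet amplitude.

    ``v_ab`` is one (time, freq) cross-wavelet matrix or a list from
    several sensor pairs, flattened along time before averaging.  For each
    frequency bin f and phase bin phi the histogram holds the mean of
    |v_ab(t, f)| over unmasked samples whose phase difference falls in that
    bin (``weight="power"`` averages |v_ab|^2 instead).  Samples with
    exactly zero amplitude (frequency bins the synchrosqueezing assigned
    nothing to) carry no mass and are not counted.  Empty bins are
    assigned ``floor_rel`` times the global maximum before the log.
    """
    if isinstance(v_ab, np.ndarray):
        v_ab = [v_ab]
    if mask is not None:
        mask = np.asarray(mask, bool)
    amps, angs = [], []
    for v in v_ab:
        v = np.asarray(v)
        if v.ndim != 2 or v.shape[1] != fgrid.n_bins:
            raise ValueError("cross-wavelet matrix must be (time, n_freq)")
        a = np.abs(v)
        if weight == "power":
            a = a ** 2
        elif weight != "amplitude":
            raise ValueError(f"unknown weight {weight!r}")
        ang = np.angle(v)
        if mask is not None:
            if mask.shape != (v.shape[0],):
                raise ValueError("mask length must match the time axis")
            a, ang = a[~mask], ang[~mask]
        amps.append(a)
        angs.append(ang)
    amp = np.concatenate(amps, axis=0)
    ang = np.concatenate(angs, axis=0)
    if amp.shape[0] == 0:
        raise ValueError("all time samples are masked; nothing to bin")
    K, M = fgrid.n_bins, pgrid.n
    idx = pgrid.bin_index(ang)                     # (T, K)
    flat = np.arange(K)[None, :] * M + idx         # bin id per (t, f)
    nonzero = amp.ravel() > 0
    total = np.bincount(flat.ravel()[nonzero], weights=amp.ravel()[nonzero],
                        minlength=K * M).reshape(K, M)
    counts = np.bincount(flat.ravel()[nonzero],
                         minlength=K * M).reshape(K, M)
    with np.errstate(invalid="ignore"):
        hist = np.where(counts > 0, total / np.maximum(counts, 1), 0.0)
    top = hist.max()
    floor = floor_rel * top if top > 0 else np.finfo(float).tiny
    y = np.log(np.maximum(hist, floor))
    return Spectrum2D(y, fgrid, pgrid, power=hist, counts=counts,
                      meta=dict(meta or {}))


def _check_phase(phi):
    phi = np.asarray(phi, float)
    if np.any(phi <= -np.pi) or np.any(phi > np.pi):
        raise ValueError("phase must lie in (-pi, pi]; normalize first")
    return phi


def phase_to_velocity(phi, f, d: float):
    """Apparent propagation velocity u = d * 2*pi*f / phi (cm/s).

    phi = 0 (synchronous) maps to +/-inf; use :func:`pace_of` for a
    modeling-friendly quantity there.
    """
    phi = _check_phase(phi)
    f = np.asarray(f, float)
    if d <= 0:
        raise ValueError("sensor separation d must be positive")
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    with np.errstate(divide="ignore"):
        u = d * 2.0 * np.pi * f / phi
    return u


def velocity_to_phase(u, f, d: float):
    """Inverse of :func:`phase_to_velocity`: phi = d * 2*pi*f / u."""
    if d <= 0:
        raise ValueError("sensor separation d must be positive")
    with np.errstate(divide="ignore"):
        return d * 2.0 * np.pi * np.asarray(f, float) / np.asarray(u, float)


def pace_of(phi, f, d: float):
    """Pace (inverse velocity, s/cm): phi / (d * 2*pi*f); 0 when phi = 0."""
    phi = _check_phase(phi)
    f = np.asarray(f, float)
    if d <= 0:
        raise ValueError("sensor separation d must be positive")
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    return phi / (d * 2.0 * np.pi * f)


class CrossSpectrum:
    """sklearn-style transformer: recording -> 2D frequency x phase response.

    All adjacent channel pairs are cross-correlated (separation = sensor
    spacing), ordered proximal-first so positive phase difference means
    antegrade propagation, and flattened before binning.  Defaults follow
    the 2D analysis resolution: 17 frequency bins, 18 phase bins.
    """

    def __init__(self, fmin_cpm: float = 1.0 / 16.0, fmax_cpm: float = 16.0,
                 n_freq: int = 17, n_phase: int = 18,
                 voices_per_octave: int = 16, omega0: float = 6.0,
                 floor_rel: float = 1e-12, weight: str = "amplitude",
                 clip_hook=None):
        self.fmin_cpm = fmin_cpm
        self.fmax_cpm = fmax_cpm
        self.n_freq = n_freq
        self.n_phase = n_phase
        self.voices_per_octave = voices_per_octave
        self.omega0 = omega0
        self.floor_rel = floor_rel
        self.weight = weight
        self.clip_hook = clip_hook

    _param_names = ("fmin_cpm", "fmax_cpm", "n_freq", "n_phase",
                    "voices_per_octave", "omega0", "floor_rel", "weight",
                    "clip_hook")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        self.fgrid_ = FrequencyGrid.from_band(self.fmin_cpm, self.fmax_cpm,
                                              self.n_freq)
        self.pgrid_ = PhaseGrid(self.n_phase)
        return self

    def transform(self, rec: PressureRecording) -> Spectrum2D:
        return self.spectrum2d(rec)

    def fit_transform(self, rec: PressureRecording, y=None):
        return self.fit().transform(rec)

    def spectrum2d(self, rec: PressureRecording) -> Spectrum2D:
        """Recording -> 2D log response from all adjacent sensor pairs."""
        if not hasattr(self, "fgrid_"):
            self.fit()
        cwt_tf = SynchrosqueezedCWT(
            fmin_cpm=self.fmin_cpm, fmax_cpm=self.fmax_cpm,
            n_freq=self.n_freq, voices_per_octave=self.voices_per_octave,
            omega0=self.omega0, clip_hook=self.clip_hook)
        spectra = cwt_tf.transform(rec)
        pairs = [cross_wavelet(spectra[c], spectra[c + 1])
                 for c in range(len(spectra) - 1)]
        return phase_histogram(pairs, self.pgrid_, self.fgrid_,
                               mask=rec.mask, floor_rel=self.floor_rel,
                               weight=self.weight, meta=rec.meta.as_dict())
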