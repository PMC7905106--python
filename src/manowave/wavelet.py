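"""Continuous wavelet transform, synchrosqueezing and global power spectra.

The transform decomposes each pressure channel x(t) into time-scale
coefficients w(t, s) by FFT convolution with a Morlet wavelet specified in
the frequency domain,

    w(t, s) = ifft[ X(omega) * sqrt(s) * Psi*(s * omega) ](t),

then reassigns coefficients from scales to a fixed geometric frequency grid
via synchrosqueezing: each w(t, s)/s is added into the frequency bin that
contains the instantaneous frequency (1/2pi) d/dt unwrap(angle w(t, s)).
Averaging |v(t, f)|^2 over (unmasked) time -- and over channels, by
flattening channels into one long time axis -- gives the global wavelet
power spectrum, whose natural log is the 1D statistical response.

Colonic motor patterns of interest live between 1/16 and 16 cycles/min
(cpm), the default analysis band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import PressureRecording, RecordingMeta

__all__ = [
    "FrequencyGrid",
    "ScaleGrid",
    "WaveletSpectrum",
    "Spectrum1D",
    "morlet_ft",
    "cwt",
    "apply_harmonic_clip",
    "synchrosqueeze",
    "global_power",
    "SynchrosqueezedCWT",
]

CPM = 1.0 / 60.0  # Hz per cycle-per-minute


@dataclass
class FrequencyGrid:
    """Geometrically spaced frequency bins.

    ``centers`` are K bin centers in Hz with a constant neighbor ratio;
    ``edges`` are the K+1 geometric bin edges.  Bin membership is half-open:
    a frequency x belongs to bin k iff edges[k] <= x < edges[k+1].
    """

    centers: np.ndarray
    edges: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, float)
        self.edges = np.asarray(self.edges, float)
        if self.centers.ndim != 1 or len(self.centers) < 2:
            raise ValueError("need at least 2 frequency bins")
        if len(self.edges) != len(self.centers) + 1:
            raise ValueError("edges must have K+1 entries")
        if np.any(np.diff(self.centers) <= 0) or np.any(np.diff(self.edges) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        r = np.diff(np.log(self.centers))
        if not np.allclose(r, r[0], rtol=1e-6):
            raise ValueError("frequency centers must be geometrically spaced")

    @classmethod
    def from_band(cls, fmin_cpm: float = 1.0 / 16.0, fmax_cpm: float = 16.0,
                  n: int = 33) -> "FrequencyGrid":
        """Grid of ``n`` log-spaced centers spanning [fmin, fmax] cpm."""
        if fmin_cpm <= 0 or fmax_cpm <= fmin_cpm:
            raise ValueError("need 0 < fmin_cpm < fmax_cpm")
        centers = np.geomspace(fmin_cpm * CPM, fmax_cpm * CPM, n)
        half = 0.5 * (np.log(centers[1]) - np.log(centers[0]))
        edges = np.exp(np.concatenate([np.log(centers) - half,
                                       [np.log(centers[-1]) + half]]))
        return cls(centers, edges)

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    @property
    def centers_cpm(self) -> np.ndarray:
        return self.centers / CPM

    def bin_index(self, freq) -> np.ndarray:
        """Half-open bin membership; -1 where outside all bins."""
        idx = np.searchsorted(self.edges, freq, side="right") - 1
        idx = np.asarray(idx)
        out = np.where((idx >= 0) & (idx < self.n_bins)
                       & (np.asarray(freq) < self.edges[-1]), idx, -1)
        return out


@dataclass
class ScaleGrid:
    """Logarithmically spaced wavelet scales (seconds) plus the mother
    wavelet shape (Morlet, center angular frequency ``omega0``)."""

    scales: np.ndarray
    wavelet: str = "morlet"
    omega0: float = 6.0

    def __post_init__(self):
        self.scales = np.asarray(self.scales, float)
        if len(self.scales) < 2 or np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing, length >= 2")
        if self.wavelet != "morlet":
            raise ValueError("only the Morlet mother wavelet is implemented")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")

    @classmethod
    def for_grid(cls, grid: FrequencyGrid, voices_per_octave: int = 16,
                 omega0: float = 6.0) -> "ScaleGrid":
        """Scales whose mapped frequencies cover the grid edges."""
        f_lo, f_hi = grid.edges[0], grid.edges[-1]
        n_oct = np.log2(f_hi / f_lo)
        L = int(np.ceil(n_oct * voices_per_octave)) + 1
        freqs = np.geomspace(f_lo, f_hi, L)
        scales = omega0 / (2.0 * np.pi * freqs[::-1])
        return cls(scales, "morlet", omega0)

    @property
    def frequencies(self) -> np.ndarray:
        """Center frequency (Hz) mapped to each scale."""
        return self.omega0 / (2.0 * np.pi * self.scales)


@dataclass
class WaveletSpectrum:
    """Synchrosqueezed coefficients v(t, f) for one channel."""

    v: np.ndarray                  # complex, (n_time, n_bins)
    grid: FrequencyGrid
    fs: float
    mask: np.ndarray | None = None  # True = excluded sample

    def __post_init__(self):
        self.v = np.asarray(self.v)
        if self.v.ndim != 2 or self.v.shape[1] != self.grid.n_bins:
            raise ValueError("v must be (n_time, n_freq_bins)")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("wavelet spectrum contains non-finite values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != (self.v.shape[0],):
                raise ValueError("mask length must match the time axis")


@dataclass
class Spectrum1D:
    """Log global wavelet power over the frequency grid; one statistical
    observation."""

    y: np.ndarray
    grid: FrequencyGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        if self.y.shape != (self.grid.n_bins,):
            raise ValueError("y length must equal the number of bins")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("spectrum contains non-finite values")


def morlet_ft(xi: np.ndarray, omega0: float = 6.0) -> np.ndarray:
    """Frequency-domain Morlet wavelet (analytic: zero for xi <= 0)."""
    psi = np.zeros_like(xi)
    pos = xi > 0
    psi[pos] = np.pi ** -0.25 * np.exp(-0.5 * (xi[pos] - omega0) ** 2)
    return psi


def cwt(signal: np.ndarray, fs: float, scales: ScaleGrid) -> np.ndarray:
    """FFT-based continuous wavelet transform.

    Returns the complex (n_time, n_scales) coefficient matrix.  The signal
    is mean-removed and zero-padded to the next power of two; the padded
    region is discarded.
    """
    x = np.asarray(signal, float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("signal must be 1D with at least 4 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    nyquist = fs / 2.0
    freqs = scales.frequencies
    if np.all(freqs >= nyquist) or np.all(freqs <= 0):
        raise ValueError(
            "no scale maps to an admissible frequency below Nyquist "
            f"({nyquist:g} Hz) at fs={fs:g}")
    n = len(x)
    npad = 1 << int(np.ceil(np.log2(n)))
    if npad == n:
        npad *= 2
    xpad = np.zeros(npad)
    xpad[:n] = x - x.mean()
    X = np.fft.fft(xpad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=1.0 / fs)
    out = np.empty((n, len(scales.scales)), dtype=complex)
    for i, s in enumerate(scales.scales):
        W = X * np.sqrt(s) * morlet_ft(s * omega, scales.omega0)
        out[:, i] = np.fft.ifft(W)[:n]
    return out


def apply_harmonic_clip(w: np.ndarray, hook=None) -> np.ndarray:
    """Optional harmonic-artifact suppression hook.

    Harmonic clipping of the time-scale coefficients (e.g. the MesaClip
    family of algorithms) is pluggable: ``hook`` receives the (time, scale)
    matrix and must return one of identical shape.  The default is the
    identity.
    """
    if hook is None:
        return w
    out = np.asarray(hook(w))
    if out.shape != w.shape:
        raise ValueError(
            f"harmonic-clip hook changed shape {w.shape} -> {out.shape}")
    return out


def synchrosqueeze(w: np.ndarray, scales: ScaleGrid, fs: float,
                   grid: FrequencyGrid, mask: np.ndarray | None = None,
                   normalization: str = "scale") -> WaveletSpectrum:
    """Reassign time-scale coefficients to frequency bins.

    For each (t, s) the instantaneous frequency is estimated as
    (1/2pi) * d/dt of the time-unwrapped phase (central differences;
    one-sided at the edges), and w(t, s) -- weighted 1/s by default
    (``normalization="scale"``), or by s^{-3/2} * dlog(s) with
    ``normalization="density"`` -- is accumulated into the containing bin.
    Coefficients whose instantaneous frequency falls outside every bin
    (including negative estimates) are discarded.
    """
    w = np.asarray(w)
    if not np.all(np.isfinite(w)):
        raise ValueError("wavelet coefficients contain non-finite values")
    n_time, n_scales = w.shape
    if n_scales != len(scales.scales):
        raise ValueError("scale axis does not match the scale grid")
    phase = np.unwrap(np.angle(w), axis=0)
    inst_freq = np.gradient(phase, axis=0) * fs / (2.0 * np.pi)
    if normalization == "scale":
        weights = 1.0 / scales.scales
    elif normalization == "density":
        dls = np.gradient(np.log(scales.scales))
        weights = scales.scales ** -1.5 * dls
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    coeff = w * weights[None, :]
    idx = grid.bin_index(inst_freq)
    valid = idx >= 0
    v = np.zeros((n_time, grid.n_bins), dtype=complex)
    rows = np.broadcast_to(np.arange(n_time)[:, None], w.shape)[valid]
    flat = rows * grid.n_bins + idx[valid]
    np.add.at(v.reshape(-1), flat, coeff[valid])
    return WaveletSpectrum(v, grid, fs, mask)


def global_power(spectra, floor_rel: float = 1e-12,
                 meta: dict | None = None) -> Spectrum1D:
    """Log global wavelet power, averaged over unmasked time and channels.

    ``spectra`` is one :class:`WaveletSpectrum` or a list (one per channel);
    channels are flattened into a single long time axis before averaging so
    each retained sample carries equal weight.  Bins with zero accumulated
    power are floored at ``floor_rel`` times the maximum bin power before
    the log, so the response stays finite.
    """
    if isinstance(spectra, WaveletSpectrum):
        spectra = [spectra]
    if not spectra:
        raise ValueError("no spectra given")
    grid = spectra[0].grid
    chunks = []
    for sp in spectra:
        if sp.grid.n_bins != grid.n_bins or not np.allclose(
                sp.grid.centers, grid.centers):
            raise ValueError("all spectra must share the frequency grid")
        p = np.abs(sp.v) ** 2
        if sp.mask is not None:
            p = p[~sp.mask]
        chunks.append(p)
    stacked = np.concatenate(chunks, axis=0)
    if stacked.shape[0] == 0:
        raise ValueError("all time samples are masked; nothing to average")
    power = stacked.mean(axis=0)
    top = power.max()
    floor = floor_rel * top if top > 0 else np.finfo(float).tiny
    power = np.maximum(power, floor)
    m = dict(meta or {})
    m.setdefault("nchan", len(spectra))
    return Spectrum1D(np.log(power), grid, m)


class SynchrosqueezedCWT:
    """sklearn-style transformer: recording -> synchrosqueezed spectra.

    Parameters
    ----------
    fmin_cpm, fmax_cpm : float
        Analysis band in cycles/min (default 1/16 to 16).
    n_freq : int
        Number of geometric frequency bins (default 33, the 1D analysis
        resolution; the 2D analysis uses 17).
    voices_per_octave : int
        Scale density of the underlying wavelet transform.
    omega0 : float
        Morlet shape parameter.
    normalization : str
        Synchrosqueezing weight: "scale" (w/s) or "density".
    clip_hook : callable or None
        Optional harmonic-clip plug-in applied to w(t, s) per channel.
    """

    def __init__(self, fmin_cpm: float = 1.0 / 16.0, fmax_cpm: float = 16.0,
                 n_freq: int = 33, voices_per_octave: int = 16,
                 omega0: float = 6.0, normalization: str = "scale",
                 clip_hook=None):
        self.fmin_cpm = fmin_cpm
        self.fmax_cpm = fmax_cpm
        self.n_freq = n_freq
        self.voices_per_octave = voices_per_octave
        self.omega0 = omega0
        self.normalization = normalization
        self.clip_hook = clip_hook

    _param_names = ("fmin_cpm", "fmax_cpm", "n_freq", "voices_per_octave",
                    "omega0", "normalization", "clip_hook")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        self.grid_ = FrequencyGrid.from_band(self.fmin_cpm, self.fmax_cpm,
                                             self.n_freq)
        return self

    def transform(self, rec: PressureRecording) -> list[WaveletSpectrum]:
        """Per-channel synchrosqueezed spectra of a recording."""
        if not hasattr(self, "grid_"):
            self.fit()
        scales = ScaleGrid.for_grid(self.grid_, self.voices_per_octave,
                                    self.omega0)
        out = []
        for c in range(rec.n_channels):
            w = cwt(rec.pressures[c], rec.fs, scales)
            w = apply_harmonic_clip(w, self.clip_hook)
            out.append(synchrosqueeze(w, scales, rec.fs, self.grid_,
                                      mask=rec.mask,
                                      normalization=self.normalization))
        return out

    def fit_transform(self, rec: PressureRecording, y=None):
        return self.fit().transform(rec)

    def spectrum1d(self, rec: PressureRecording) -> Spectrum1D:
        """Recording -> 1D log-power response with experimental labels."""
        spectra = self.transform(rec)
        meta = rec.meta.as_dict()
        return global_power(spectra, meta=meta)
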