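"""Basic plots: 1D credible-envelope curves and 2D frequency x phase maps.

The 2D map follows the conventional layout: synchronous activity at phase
0 in the middle, retrograde propagation left of the midline, antegrade to
the right, with dotted velocity isolines (default 1 to 100 cm/min) drawn
through the phase-velocity relation phi = d * 2*pi*f / u.
"""

from __future__ import annotations

import numpy as np

from .contrasts import ContrastResult
from .cross import velocity_to_phase

__all__ = ["plot_envelope", "plot_map2d", "plot_contrast2d"]


def plot_envelope(result: ContrastResult, freqs_cpm, ax=None,
                  n_traces: int = 200, ratio_scale: bool = True):
    """Posterior traces, 95% envelope and the ratio-1 reference line,
    frequency on the y axis (log scale)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    lr = result.log_ratio_draws
    x = np.exp(lr) if ratio_scale else lr
    band = result.ratio_band if ratio_scale else result.band
    step = max(1, lr.shape[0] // n_traces)
    ax.plot(x[::step].T, freqs_cpm, color="gray", alpha=0.08, lw=0.5)
    ax.plot(band[0], freqs_cpm, "k:", lw=1.2)
    ax.plot(band[1], freqs_cpm, "k:", lw=1.2)
    ax.axvline(1.0 if ratio_scale else 0.0, color="red", lw=1)
    ax.set_yscale("log")
    ax.set_xscale("log" if ratio_scale else "linear")
    ax.set_ylabel("frequency (cpm)")
    ax.set_xlabel("power ratio" if ratio_scale else "log power ratio")
    if result.name:
        ax.set_title(result.name, fontsize=9)
    return ax


def _velocity_isolines(ax, freqs_cpm, spacing_cm=1.0,
                       speeds_cm_min=(1, 3, 10, 30, 100)):
    f_hz = np.asarray(freqs_cpm, float) / 60.0
    for u in speeds_cm_min:
        u_cm_s = u / 60.0
        phi = velocity_to_phase(u_cm_s, f_hz, spacing_cm)
        for sign in (1.0, -1.0):
            p = sign * phi
            ok = (np.abs(p) <= np.pi)
            if ok.any():
                ax.plot(p[ok], np.asarray(freqs_cpm)[ok], ":",
                        color="white", lw=0.6, alpha=0.7)


def plot_map2d(values, freqs_cpm, phase_centers, ax=None, spacing_cm=1.0,
               cmap="viridis", label="log power"):
    """Frequency x phase map; antegrade (positive phase) to the right."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 6))
    m = ax.pcolormesh(phase_centers, freqs_cpm, values, cmap=cmap,
                      shading="nearest")
    ax.axvline(0.0, color="white", lw=0.8)
    _velocity_isolines(ax, freqs_cpm, spacing_cm)
    ax.set_yscale("log")
    ax.set_xlabel("phase difference (rad)  [retrograde | antegrade]")
    ax.set_ylabel("frequency (cpm)")
    plt.colorbar(m, ax=ax, label=label)
    return ax


def plot_contrast2d(result: ContrastResult, freqs_cpm, phase_centers,
                    ax=None, spacing_cm=1.0):
    """Median log-ratio surface with the significant region outlined."""
    import matplotlib.pyplot as plt

    kf, kh = len(freqs_cpm), len(phase_centers)
    med = result.median.reshape(kf, kh)
    sig = result.significant.reshape(kf, kh)
    ax = plot_map2d(med, freqs_cpm, phase_centers, ax=ax,
                    spacing_cm=spacing_cm, cmap="RdBu_r",
                    label="median log power ratio")
    if sig.any():
        ax.contour(phase_centers, freqs_cpm, sig.astype(float),
                   levels=[0.5], colors="white", linewidths=1.2)
    return ax
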