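"""Synthetic data: pressure recordings with known propagating content, and
response datasets drawn from the generative functional mixed model.

The recording generator emulates what 10 Hz-class high-resolution colonic
manometry looks like to the analysis: quasiperiodic *bursts* of pressure
waves (not stationary tones) at frequencies in the 1/16-16 cpm band, which
propagate along the sensor array at a controlled signed velocity (0 =
synchronous), superimposed on a resting baseline with optional slow drift,
all-channel step artifacts and white sensor noise.  Defaults mirror a
postprandial sigmoid recording: 30 channels at 1 cm spacing, 10 Hz, 1 h,
3 cpm bursts of ~3 cycles recurring every ~3 min.

The response generator runs the statistical model forward: given design
matrices and true effect functions it draws correlated subject effects,
builds the mean and scale surfaces, and samples responses from the
structured GP noise -- the ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import add_jitter, logse_gram
from .preprocess import PressureRecording, RecordingMeta

__all__ = ["WaveSpec", "SyncArtifact", "TrueEffects",
           "simulate_recording", "simulate_responses", "make_obs_table"]


@dataclass
class WaveSpec:
    """One propagating oscillatory component of a synthetic recording.

    velocity_cm_s is signed: positive = antegrade (proximal to distal),
    negative = retrograde, 0 = synchronous (no inter-channel lag).
    Bursts have a Gaussian envelope of ``cycles_per_burst`` cycles FWHM
    recurring every ``burst_interval_s`` seconds; ``burst_interval_s=None``
    produces a continuous tone.
    """

    freq_cpm: float = 3.0
    amplitude: float = 20.0
    velocity_cm_s: float = -0.5
    start_s: float = 0.0
    stop_s: float | None = None
    channels: tuple[int, int] | None = None   # half-open span, None = all
    cycles_per_burst: float = 3.0
    burst_interval_s: float | None = 180.0

    def __post_init__(self):
        if self.freq_cpm <= 0:
            raise ValueError("freq_cpm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class SyncArtifact:
    """An all-channel pressure step (strain-like artifact)."""

    time_s: float
    amplitude: float = 30.0
    duration_s: float = 5.0
    rise_s: float = 0.5


def simulate_recording(
    waves: list[WaveSpec] | None = None,
    n_channels: int = 30,
    fs: float = 10.0,
    duration_s: float = 3600.0,
    spacing_cm: float = 1.0,
    baseline_mmhg: float = 20.0,
    drift_mmhg: float = 0.0,
    sync_artifacts: list[SyncArtifact] | None = None,
    noise_sd: float = 0.5,
    seed: int | None = None,
    meta: RecordingMeta | None = None,
) -> PressureRecording:
    """Generate a channels x time pressure matrix with known content.

    Each wave contributes Gaussian-envelope oscillatory bursts with a
    per-channel time lag ``channel * spacing / velocity`` (zero when
    synchronous), so the inter-channel phase lag at the drive frequency is
    ``2*pi*f*spacing/u`` -- the inverse of the velocity formula used by the
    cross-wavelet analysis.  ``drift_mmhg`` adds a linear ramp of that total
    height over the recording; ``seed`` makes the output bit-reproducible.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if waves is None:
        waves = [WaveSpec()]
    rng = np.random.default_rng(seed)
    n_time = int(round(duration_s * fs))
    t = np.arange(n_time) / fs
    p = np.full((n_channels, n_time), float(baseline_mmhg))

    for wv in waves:
        f = wv.freq_cpm / 60.0
        stop = duration_s if wv.stop_s is None else wv.stop_s
        c0, c1 = wv.channels if wv.channels is not None else (0, n_channels)
        if wv.burst_interval_s is None:
            centers = [0.5 * (wv.start_s + stop)]
            sd = (stop - wv.start_s)  # envelope wide enough to be ~flat
        else:
            centers = np.arange(wv.start_s, stop, wv.burst_interval_s)
            centers = centers + 0.5 * wv.burst_interval_s
            fwhm = wv.cycles_per_burst / f
            sd = fwhm / 2.355
        phase0 = rng.uniform(0, 2 * np.pi)
        for c in range(c0, min(c1, n_channels)):
            if wv.velocity_cm_s == 0.0:
                lag = 0.0
            else:
                lag = c * spacing_cm / wv.velocity_cm_s
            carrier = np.cos(2 * np.pi * f * (t - lag) + phase0)
            env = np.zeros(n_time)
            for tc in np.atleast_1d(centers):
                env += np.exp(-0.5 * ((t - lag - tc) / sd) ** 2)
            env = np.minimum(env, 1.0)
            active = (t >= wv.start_s - 2 * sd) & (t <= stop + 2 * sd)
            p[c] += wv.amplitude * env * carrier * active

    if drift_mmhg:
        p += drift_mmhg * (t / duration_s)[None, :]

    for art in (sync_artifacts or []):
        ramp = np.clip((t - art.time_s) / max(art.rise_s, 1e-9), 0, 1)
        fall = np.clip((art.time_s + art.duration_s - t)
                       / max(art.rise_s, 1e-9), 0, 1)
        p += art.amplitude * np.minimum(ramp, fall)[None, :]

    if noise_sd > 0:
        p += rng.normal(0.0, noise_sd, size=p.shape)

    meta = meta or RecordingMeta(nchan=n_channels)
    return PressureRecording(p, fs=fs, spacing=spacing_cm, meta=meta)


@dataclass
class TrueEffects:
    """Ground-truth parameters for forward simulation of responses.

    ``beta`` (P x K) and ``gamma`` (Q x K) are the fixed-effect functions
    for the mean and log-scale.  Subject effects are drawn from a
    matrix-normal with between-function covariance ``sigma_b`` (E x E,
    E = effects per subject) and within-function correlation given by a
    log-SE kernel of lengthscale ``lambda_b``.  The structured residual
    kernel has amplitude ``tau_sigma`` and lengthscale ``lambda_sigma``;
    ``sigma_eps`` is the unstructured noise sd.
    """

    beta: np.ndarray
    gamma: np.ndarray
    sigma_b: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))
    lambda_b: float = 0.5
    tau_sigma: float = 0.3
    lambda_sigma: float = 0.3
    sigma_eps: float = 0.1
    offset: float = 0.0


def simulate_responses(X: np.ndarray, Z: np.ndarray, W: np.ndarray,
                       freqs: np.ndarray, truth: TrueEffects,
                       seed: int | None = None,
                       return_latent: bool = False):
    """Draw N response curves from the generative model.

    Subject effects b are drawn per subject block of Z, then
    eta = X beta + Z b + offset and log omega = W gamma; responses are
    y_i = eta_i + omega_i * r_i with r_i ~ N(0, K_sigma + sigma_eps^2 I).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    X, Z, W = np.asarray(X, float), np.asarray(Z, float), np.asarray(W, float)
    freqs = np.asarray(freqs, float)
    K = len(freqs)
    P, Q = truth.beta.shape[0], truth.gamma.shape[0]
    if truth.beta.shape != (P, K) or truth.gamma.shape != (Q, K):
        raise ValueError("beta/gamma must be (n_effects, n_gridpoints)")
    if X.shape[1] != P or W.shape[1] != Q:
        raise ValueError("design matrices do not match effect counts")

    E = truth.sigma_b.shape[0]
    eig = np.linalg.eigvalsh(truth.sigma_b)
    if np.any(eig < -1e-10):
        raise ValueError("sigma_b must be positive semidefinite")
    n_sub = Z.shape[1] // E if Z.shape[1] else 0
    if Z.shape[1] and Z.shape[1] % E:
        raise ValueError("Z column count is not a multiple of the "
                         "effects-per-subject block size")

    Kb = add_jitter(logse_gram(freqs, 1.0, truth.lambda_b))
    Lb = np.linalg.cholesky(Kb)
    Ab = np.linalg.cholesky(truth.sigma_b + 1e-12 * np.eye(E)) \
        if E and truth.sigma_b.any() else np.zeros((E, E))
    b = np.zeros((Z.shape[1], K))
    for s in range(n_sub):
        eps = rng.standard_normal((E, K))
        b[s * E:(s + 1) * E] = Ab @ eps @ Lb.T

    eta = X @ truth.beta + (Z @ b if Z.shape[1] else 0.0) + truth.offset
    omega = np.exp(W @ truth.gamma)

    C = add_jitter(
        logse_gram(freqs, truth.tau_sigma, truth.lambda_sigma),
        truth.tau_sigma) + truth.sigma_eps ** 2 * np.eye(K)
    Lc = np.linalg.cholesky(C)
    resid = rng.standard_normal((X.shape[0], K)) @ Lc.T
    Y = eta + omega * resid
    if return_latent:
        return Y, {"eta": eta, "omega": omega, "b": b, "C": C}
    return Y


def make_obs_table(n_healthy: int = 11, n_patient: int = 12,
                   regions=("descending", "sigmoid"),
                   meals=("preprandial", "postprandial"),
                   nchan_range=(24, 36), seed: int = 0,
                   drop_cells: int = 0):
    """Observation table for a factorial manometry study design.

    One row per subject x region x meal cell, with a per-cell channel
    count.  ``drop_cells`` removes that many randomly chosen cells to
    emulate incomplete designs.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for g, n in (("healthy", n_healthy), ("patient", n_patient)):
        for i in range(n):
            subj = f"{g[0]}{i:02d}"
            for r in regions:
                nch = int(rng.integers(*nchan_range))
                for m in meals:
                    rows.append({"subject": subj, "group": g, "region": r,
                                 "meal": m, "nchan": nch})
    df = pd.DataFrame(rows)
    if drop_cells:
        keep = rng.permutation(len(df))[:-drop_cells]
        df = df.iloc[np.sort(keep)].reset_index(drop=True)
    return df
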