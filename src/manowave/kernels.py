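"""Gaussian-process covariance kernels on frequency and phase domains.

Two kernels are used throughout:

* a squared-exponential kernel in *log frequency*,
  ``k(f, f') = tau^2 exp(-|ln f - ln f'|^2 / (2 lambda^2))``, appropriate for
  responses indexed by geometrically spaced frequency bins, and
* a periodic kernel on phase differences,
  ``k(phi, phi') = exp(-2 sin^2(|phi - phi'|/2) / lambda_phi^2)``, which
  identifies phases 2*pi apart.

The 2D frequency x phase kernel is their product and therefore separable:
its Gram matrix on a product grid is a Kronecker product of the two 1D
Gram matrices, which the model and grid-refinement code exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelSpec",
    "kernel_logse",
    "kernel_periodic",
    "kernel_2d",
    "logse_gram",
    "periodic_gram",
    "gram_2d",
    "add_jitter",
]

JITTER_REL = 1e-8


@dataclass
class KernelSpec:
    """Kernel configuration for one latent effect function.

    ``correlation_only`` forces tau = 1 so the kernel builds a correlation
    matrix; used for group-level effects whose variance lives in the
    between-function covariance instead (a free tau there would make the
    model non-identifiable).
    """

    kind: str = "logse"              # "logse" | "logse_periodic"
    tau: float = 1.0
    lambda_f: float = 1.0
    lambda_phi: float | None = None
    correlation_only: bool = False

    def __post_init__(self):
        if self.kind not in ("logse", "logse_periodic"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.correlation_only:
            self.tau = 1.0
        if self.tau <= 0 or self.lambda_f <= 0:
            raise ValueError("kernel hyperparameters must be positive")
        if self.kind == "logse_periodic":
            if self.lambda_phi is None or self.lambda_phi <= 0:
                raise ValueError("logse_periodic requires positive lambda_phi")


def kernel_logse(f, f2, tau: float = 1.0, lam: float = 1.0):
    """Log-space squared-exponential covariance between frequencies (Hz)."""
    f, f2 = np.asarray(f, float), np.asarray(f2, float)
    if np.any(f <= 0) or np.any(f2 <= 0):
        raise ValueError("frequencies must be positive")
    if tau <= 0 or lam <= 0:
        raise ValueError("tau and lambda must be positive")
    d = np.log(f) - np.log(f2)
    return tau ** 2 * np.exp(-(d ** 2) / (2.0 * lam ** 2))


def kernel_periodic(phi, phi2, lam_phi: float = 1.0):
    """Periodic covariance between phase differences (radians)."""
    if lam_phi <= 0:
        raise ValueError("lambda_phi must be positive")
    d = np.abs(np.asarray(phi, float) - np.asarray(phi2, float))
    return np.exp(-2.0 * np.sin(0.5 * d) ** 2 / lam_phi ** 2)


def kernel_2d(f, phi, f2, phi2, tau: float = 1.0,
              lam_f: float = 1.0, lam_phi: float = 1.0):
    """Product kernel on (frequency, phase) pairs: logSE x periodic."""
    return (kernel_logse(f, f2, tau, lam_f)
            * kernel_periodic(phi, phi2, lam_phi))


def logse_gram(f, tau: float = 1.0, lam: float = 1.0) -> np.ndarray:
    f = np.asarray(f, float)
    return kernel_logse(f[:, None], f[None, :], tau, lam)


def periodic_gram(phi, lam_phi: float = 1.0) -> np.ndarray:
    phi = np.asarray(phi, float)
    return kernel_periodic(phi[:, None], phi[None, :], lam_phi)


def gram_2d(f, phi, tau: float = 1.0, lam_f: float = 1.0,
            lam_phi: float = 1.0) -> np.ndarray:
    """Dense Gram matrix on the product grid, ordered frequency-major
    (row index = i_f * len(phi) + i_phi), equal to
    ``kron(logse_gram, periodic_gram)``."""
    return np.kron(logse_gram(f, tau, lam_f), periodic_gram(phi, lam_phi))


def add_jitter(K: np.ndarray, tau: float = 1.0,
               rel: float = JITTER_REL) -> np.ndarray:
    """Return K + rel * tau^2 * I for numerically safe factorizations."""
    return K + rel * tau ** 2 * np.eye(K.shape[0])
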