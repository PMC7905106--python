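"""Latent Gaussian-process function-on-scalar mixed-effects model.

Each observation i is a response function y_i on a fixed grid (a log-power
curve over frequency bins, or a surface over frequency x phase bins),
modeled as

    y_i(x) ~ GP(eta_i(x),  omega_i(x) omega_i(x') (k_sigma(x,x') + sig_eps^2))
    eta_i(x)      = X_i beta(x) + Z_i b(x) + o
    log omega_i(x) = W_i gamma(x) + U_i u(x)

with iid GP priors on the population effect functions beta_p, gamma_q and a
matrix-normal prior on the per-subject effect functions b (between-function
covariance Sigma_b shared across subjects, within-function correlation from
a tau=1 kernel).  Standardizing residuals by omega_i reduces the likelihood
to a single zero-mean GP with covariance C = K_sigma + sig_eps^2 I shared
by all observations: one Cholesky of C serves every observation in the 1D
case, and in the 2D case the Kronecker structure K_sigma = KF (x) KH is
separated from the white-noise term through the eigendecompositions of the
two factors.

Hyperpriors: lambda ~ Lognormal(0,1) for effect kernels and
lambda_sigma ~ Lognormal(-0.7,1) constrained below the smallest effect
lengthscale (reparameterized multiplicatively, so no rejection is needed);
tau ~ Gamma(2,1); sig_eps and the Sigma_b standard deviations ~
Half-Normal(1); the Sigma_b correlation ~ LKJ(2); in the 2D model a shared
rho ~ Beta(2,2) correlates each kernel's log lambda_f with its log
lambda_phi through a Gaussian copula.

Inference is adaptive HMC (NUTS) on the unconstrained scale with all
latent functions non-centered (whitened through the kernel Cholesky /
Kronecker factors).  Chains are zero-initialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky as sp_cholesky, solve_triangular

from . import autodiff as ad
from .design import DesignMatrices, build_design_matrices
from .hmc import NutsConfig, nuts_chain
from .kernels import JITTER_REL, add_jitter, logse_gram, periodic_gram
from .wavelet import FrequencyGrid, Spectrum1D
from .cross import PhaseGrid, Spectrum2D

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "structured_covariance",
    "log_likelihood",
    "log_likelihood_2d",
    "kron_inv",
    "fit_hmc",
    "GPFunctionalMixedModel",
]

LN2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# specification containers
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Grid geometry, offset policy and prior configuration for one fit."""

    fgrid: FrequencyGrid
    pgrid: PhaseGrid | None = None          # present => 2D model
    offset: str | float | np.ndarray = "mean"
    lambda_mu: float = 0.0                  # Lognormal(mu, sd) for lambdas
    lambda_sd: float = 1.0
    lambda_sigma_mu: float = -0.7
    lambda_sigma_sd: float = 1.0
    tau_shape: float = 2.0                  # Gamma(shape, rate) for taus
    tau_rate: float = 1.0
    lkj_eta: float = 2.0

    @property
    def is_2d(self) -> bool:
        return self.pgrid is not None

    @property
    def n_points(self) -> int:
        k = self.fgrid.n_bins
        return k * self.pgrid.n if self.pgrid is not None else k


@dataclass
class PosteriorDraws:
    """Posterior draws of all latent effect functions and hyperparameters.

    Function draws live on the coarse sampling grid, frequency-major for 2D
    fits (gridpoint = i_f * n_phase + i_phi).  ``hyper`` maps a parameter
    name to a (n_draws,) or (n_draws, dim) array.
    """

    beta: np.ndarray                 # (draws, P, n_points)
    b: np.ndarray                    # (draws, J, n_points)
    gamma: np.ndarray                # (draws, Q, n_points)
    hyper: dict
    diagnostics: dict
    spec: ModelSpec | None = None
    dm: DesignMatrices | None = None
    offset: float | np.ndarray = 0.0

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


# ---------------------------------------------------------------------------
# structured likelihood (plain numpy; public operations and test oracles)
# ---------------------------------------------------------------------------

def structured_covariance(freqs, tau_sigma, lambda_sigma, sigma_eps):
    """C = K_sigma + sig_eps^2 I on a 1D frequency grid (with jitter)."""
    K = add_jitter(logse_gram(freqs, tau_sigma, lambda_sigma), tau_sigma)
    return K + sigma_eps ** 2 * np.eye(len(np.atleast_1d(freqs)))


def _chol_or_raise(C):
    try:
        return sp_cholesky(C, lower=True)
    except np.linalg.LinAlgError:
        ev = np.linalg.eigvalsh(C)[0]
        raise np.linalg.LinAlgError(
            f"covariance is not positive definite (smallest eigenvalue "
            f"{ev:.3e})")


def log_likelihood(Y, Eta, Omega, C):
    """Joint log density of response curves under the structured model.

    Parameters are (N, K) arrays of responses, means and positive scale
    functions, plus the shared (K, K) standardized-residual covariance
    C = K_sigma + sig_eps^2 I.  Equivalent to summing the dense MVN logpdf
    of y_i under N(eta_i, D_omega_i C D_omega_i); evaluated with a single
    Cholesky of C plus the change-of-variables term -sum log omega.
    """
    Y, Eta, Omega = (np.atleast_2d(np.asarray(a, float))
                     for a in (Y, Eta, Omega))
    if np.any(Omega <= 0):
        raise ValueError("omega must be strictly positive")
    N, K = Y.shape
    L = _chol_or_raise(C)
    R = (Y - Eta) / Omega
    Q = solve_triangular(L, R.T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return (-0.5 * np.sum(Q ** 2) - 0.5 * N * (logdet + K * LN2PI)
            - np.sum(np.log(Omega)))


def log_likelihood_2d(Y, Eta, Omega, KF, KH, sigma_eps):
    """2D (Kronecker) version of :func:`log_likelihood`.

    K_sigma = KF (x) KH with responses flattened frequency-major, so
    C = (QF (x) QH) diag(lf (x) lh + sig_eps^2) (QF (x) QH)^T via the
    eigendecompositions of the two factors; no K*K factorization of the
    full grid is formed.
    """
    Y, Eta, Omega = (np.atleast_2d(np.asarray(a, float))
                     for a in (Y, Eta, Omega))
    if np.any(Omega <= 0):
        raise ValueError("omega must be strictly positive")
    N = Y.shape[0]
    kf, kh = KF.shape[0], KH.shape[0]
    lf, QF = np.linalg.eigh(KF)
    lh, QH = np.linalg.eigh(KH)
    evals = np.outer(lf, lh).ravel() + sigma_eps ** 2
    if np.any(evals <= 0):
        raise np.linalg.LinAlgError(
            f"covariance is not positive definite (smallest eigenvalue "
            f"{evals.min():.3e})")
    R = (Y - Eta) / Omega
    T = np.einsum("fi,nfh,hj->nij", QF, R.reshape(N, kf, kh), QH)
    quad = np.sum(T.reshape(N, -1) ** 2 / evals[None, :])
    logdet = np.sum(np.log(evals))
    return (-0.5 * quad - 0.5 * N * (logdet + kf * kh * LN2PI)
            - np.sum(np.log(Omega)))


def kron_inv(A, B):
    """(A (x) B)^{-1} = A^{-1} (x) B^{-1} without forming the product."""
    return np.kron(np.linalg.inv(A), np.linalg.inv(B))


# ---------------------------------------------------------------------------
# unconstrained parameterization
# ---------------------------------------------------------------------------

class _Layout:
    """Slice bookkeeping for the flat unconstrained parameter vector."""

    def __init__(self):
        self.slices = {}
        self.size = 0

    def add(self, name, n):
        self.slices[name] = slice(self.size, self.size + n)
        self.size += n

    def get(self, theta, name):
        return theta[self.slices[name]]


def _build_layout(P, Q, S, E, n_points, is_2d):
    lay = _Layout()
    n_lam = 2 if is_2d else 1
    lay.add("log_tau_beta", P)
    lay.add("z_lam_beta", P * n_lam)
    lay.add("log_tau_gamma", Q)
    lay.add("z_lam_gamma", Q * n_lam)
    if S:
        lay.add("z_lam_b", n_lam)
        lay.add("log_sd_b", E)
        if E > 1:
            lay.add("lkj_y", E * (E - 1) // 2)
    lay.add("log_tau_sigma", 1)
    lay.add("zeta_lam_sigma", n_lam)
    lay.add("log_sigma_eps", 1)
    if is_2d:
        lay.add("logit_rho", 1)
    lay.add("beta_til", P * n_points)
    lay.add("gamma_til", Q * n_points)
    if S:
        lay.add("b_til", S * E * n_points)
    return lay


def _lkj_cholesky(y, E, eta):
    """Unconstrained vector -> (L Vars by row, log prior + log |Jacobian|).

    Canonical-partial-correlation construction; returns the lower Cholesky
    factor of an E x E correlation matrix as nested scalar Vars plus the
    LKJ(eta) log density including the transform Jacobian.
    """
    z = ad.tanh(y)
    logj = ad.log(1.0 - ad.square(z) + 1e-15).sum()
    L = [[None] * E for _ in range(E)]
    logdet_terms = []
    idx = 0
    for i in range(E):
        acc = None
        for j in range(i):
            w2 = 1.0 - acc if acc is not None else ad.constant(1.0)
            w = ad.sqrt(w2 + 1e-15)
            lij = z[idx] * w
            logdet_terms.append(ad.log(w + 1e-15))
            L[i][j] = lij
            acc = ad.square(lij) if acc is None else acc + ad.square(lij)
            idx += 1
        w2 = 1.0 - acc if acc is not None else ad.constant(1.0)
        L[i][i] = ad.sqrt(w2 + 1e-15)
    logp = logj
    for t in logdet_terms:
        logp = logp + t
    # LKJ(eta) on the correlation matrix: det(R)^(eta-1) = prod L_ii^2(eta-1)
    for i in range(1, E):
        logp = logp + (2.0 * (eta - 1.0)) * ad.log(L[i][i])
    # assemble matrix
    basis = np.zeros((E, E, E, E))
    mat = None
    for i in range(E):
        for j in range(i + 1):
            e = np.zeros((E, E))
            e[i, j] = 1.0
            term = L[i][j] * ad.constant(e)
            mat = term if mat is None else mat + term
    return mat, logp


def _halfnormal_logp(log_s):
    """Half-Normal(1) on s with log jacobian, s = exp(log_s)."""
    s = ad.exp(log_s)
    return (-0.5 * ad.square(s) + log_s).sum()


def _gamma_logp(log_t, shape, rate):
    """Gamma(shape, rate) on t with log jacobian, t = exp(log_t)."""
    t = ad.exp(log_t)
    return (shape * log_t - rate * t).sum()


class _LogPosterior:
    """Differentiable log posterior for the 1D and 2D models."""

    def __init__(self, spec: ModelSpec, dm: DesignMatrices, Y: np.ndarray,
                 offset, prior_only: bool = False):
        self.spec = spec
        self.dm = dm
        self.prior_only = prior_only
        self.N, self.n_points = Y.shape
        self.P = dm.X.shape[1]
        self.Q = dm.W.shape[1]
        self.E = dm.effects_per_group
        self.S = len(dm.groups)
        self.is_2d = spec.is_2d
        self.kf = spec.fgrid.n_bins
        self.kh = spec.pgrid.n if spec.pgrid is not None else 1
        self.layout = _build_layout(self.P, self.Q, self.S, self.E,
                                    self.n_points, self.is_2d)

        self.Yc = ad.constant(Y - offset)
        self.Xc = ad.constant(dm.X)
        self.Wc = ad.constant(dm.W)
        self.Zc = ad.constant(dm.Z) if self.S else None
        # squared log-frequency distances (and phase distances for 2D)
        lf = np.log(spec.fgrid.centers)
        self._d2f = -0.5 * (lf[:, None] - lf[None, :]) ** 2
        self.D2f = ad.constant(self._d2f)
        if self.is_2d:
            ph = spec.pgrid.centers
            self._s2h = (-2.0
                         * np.sin(0.5 * np.abs(ph[:, None] - ph[None, :]))
                         ** 2)
            self.S2h = ad.constant(self._s2h)
        self.If = ad.constant(np.eye(self.kf))
        self.Ih = ad.constant(np.eye(self.kh)) if self.is_2d else None

    # -- kernel factor helpers (batched over a vector of lengthscales) ---
    def _corr_f(self, lam):
        """(..., kf, kf) correlation matrices for lengthscale(s) lam."""
        if lam.value.ndim == 0:
            return ad.exp(self.D2f / ad.square(lam)) + JITTER_REL * self.If
        n = lam.shape[0]
        inv2 = (lam ** -2.0).reshape(n, 1, 1)
        return ad.exp(self.D2f * inv2) \
            + ad.constant(JITTER_REL * np.eye(self.kf)[None, :, :])

    def _corr_h(self, lam):
        if lam.value.ndim == 0:
            return ad.exp(self.S2h / ad.square(lam)) + JITTER_REL * self.Ih
        n = lam.shape[0]
        inv2 = (lam ** -2.0).reshape(n, 1, 1)
        return ad.exp(self.S2h * inv2) \
            + ad.constant(JITTER_REL * np.eye(self.kh)[None, :, :])

    def _lambda_pairs(self, z, n, rho_chol):
        """Whitened normals -> lengthscale vectors.

        Returns a tuple of Vars: (lam_f,) for 1D or (lam_f, lam_phi) for
        2D, each of length n; in 2D the pair's normals are correlated by
        the copula Cholesky ``rho_chol = (r, sqrt(1 - r^2))``.
        """
        mu, sd = self.spec.lambda_mu, self.spec.lambda_sd
        if not self.is_2d:
            return (ad.exp(mu + sd * z),)
        zm = z.reshape(n, 2)
        e1 = zm[:, 0]
        e2 = zm[:, 1]
        if rho_chol is not None:
            r, w = rho_chol
            e2 = r * e1 + w * e2
        return ad.exp(mu + sd * e1), ad.exp(mu + sd * e2)

    def _whiten_batch(self, til, lams, tau=None):
        """Non-centered latent functions, batched over effects.

        ``til`` is (n, n_points) whitened coefficients; returns (n,
        n_points) function values L_f til (L_h^T) scaled by tau.
        """
        n = til.shape[0]
        Lf = ad.cholesky(self._corr_f(lams[0]))
        if self.is_2d:
            Lh = ad.cholesky(self._corr_h(lams[1]))
            t3 = til.reshape(n, self.kf, self.kh)
            f = (Lf @ t3 @ Lh.mT).reshape(n, self.n_points)
        else:
            f = (Lf @ til.reshape(n, self.kf, 1)).reshape(n, self.kf)
        if tau is not None:
            f = f * tau.reshape(n, 1)
        return f

    # -- the log posterior ------------------------------------------------
    def __call__(self, theta_np):
        theta = ad.Var(theta_np)
        lay = self.layout
        sp = self.spec
        n_lam = 2 if self.is_2d else 1
        logp = ad.constant(0.0)

        # copula correlation (2D only)
        rho_chol = None
        if self.is_2d:
            lr = lay.get(theta, "logit_rho")[0]
            rho = ad.sigmoid(lr)
            a, b_ = 2.0, 2.0  # Beta(2,2) with logit jacobian
            logp = logp + a * ad.log(rho) + b_ * ad.log(1.0 - rho)
            w = ad.sqrt(1.0 - ad.square(rho) + 1e-12)
            rho_chol = (rho, w)

        # fixed-effect taus and lambdas
        log_tau_b = lay.get(theta, "log_tau_beta")
        log_tau_g = lay.get(theta, "log_tau_gamma")
        logp = logp + _gamma_logp(log_tau_b, sp.tau_shape, sp.tau_rate)
        logp = logp + _gamma_logp(log_tau_g, sp.tau_shape, sp.tau_rate)
        z_lam_b = lay.get(theta, "z_lam_beta")
        z_lam_g = lay.get(theta, "z_lam_gamma")
        logp = logp - 0.5 * (ad.square(z_lam_b).sum()
                             + ad.square(z_lam_g).sum())

        lam_beta = self._lambda_pairs(z_lam_b, self.P, rho_chol)
        lam_gamma = self._lambda_pairs(z_lam_g, self.Q, rho_chol)
        tau_beta = ad.exp(log_tau_b)
        tau_gamma = ad.exp(log_tau_g)

        lam_b = None
        if self.S:
            z_lam_rb = lay.get(theta, "z_lam_b")
            logp = logp - 0.5 * ad.square(z_lam_rb).sum()
            lam_b = self._lambda_pairs(z_lam_rb, 1, rho_chol)

        # noise lengthscale(s) constrained below every effect lengthscale
        # in the matching domain (frequency / phase)
        zeta = lay.get(theta, "zeta_lam_sigma")
        lam_sigma = []
        for i in range(n_lam):
            lam_min = ad.vmin(lam_beta[i])
            if self.Q:
                lam_min = ad.minimum2(lam_min, ad.vmin(lam_gamma[i]))
            if lam_b is not None:
                lam_min = ad.minimum2(lam_min, ad.vmin(lam_b[i]))
            sig = ad.sigmoid(zeta[i])
            ls = lam_min * sig
            # Lognormal(-0.7, 1) density on lam_sigma + Jacobian of
            # zeta -> lam_sigma (= lam_min * sig * (1 - sig))
            lls = ad.log(ls)
            logp = logp - 0.5 * ad.square(
                (lls - sp.lambda_sigma_mu) / sp.lambda_sigma_sd) - lls
            logp = logp + ad.log(lam_min) + ad.log(sig) + ad.log(1.0 - sig)
            lam_sigma.append(ls)

        log_tau_s = lay.get(theta, "log_tau_sigma")
        logp = logp + _gamma_logp(log_tau_s, sp.tau_shape, sp.tau_rate)
        tau_sigma = ad.exp(log_tau_s[0])
        log_se = lay.get(theta, "log_sigma_eps")
        logp = logp + _halfnormal_logp(log_se)
        sigma_eps = ad.exp(log_se[0])

        # subject-effect covariance Sigma_b = diag(sd) R diag(sd)
        A_b = None
        if self.S:
            log_sd = lay.get(theta, "log_sd_b")
            logp = logp + _halfnormal_logp(log_sd)
            sd = ad.exp(log_sd)
            if self.E > 1:
                Lcorr, lkj_lp = _lkj_cholesky(lay.get(theta, "lkj_y"),
                                              self.E, sp.lkj_eta)
                logp = logp + lkj_lp
                A_b = sd.reshape(self.E, 1) * Lcorr
            else:
                A_b = sd.reshape(1, 1)

        # latent functions (non-centered, batched over effects)
        npts = self.n_points
        bt = lay.get(theta, "beta_til").reshape(self.P, npts)
        logp = logp - 0.5 * ad.square(bt).sum()
        Beta = self._whiten_batch(bt, lam_beta, tau_beta)
        eta = self.Xc @ Beta
        if self.Q:
            gt = lay.get(theta, "gamma_til").reshape(self.Q, npts)
            logp = logp - 0.5 * ad.square(gt).sum()
            Gamma = self._whiten_batch(gt, lam_gamma, tau_gamma)
            log_omega = self.Wc @ Gamma
        else:
            log_omega = ad.constant(np.zeros((self.N, npts)))

        if self.S:
            b_til = lay.get(theta, "b_til")
            logp = logp - 0.5 * ad.square(b_til).sum()
            Lbf = ad.cholesky(self._corr_f(lam_b[0][0]))
            if self.is_2d:
                Lbh = ad.cholesky(self._corr_h(lam_b[1][0]))
                t3 = b_til.reshape(self.S * self.E, self.kf, self.kh)
                Wfun = (Lbf @ t3 @ Lbh.mT).reshape(self.S, self.E, npts)
            else:
                t3 = b_til.reshape(self.S * self.E, self.kf, 1)
                Wfun = (Lbf @ t3).reshape(self.S, self.E, npts)
            B = (A_b @ Wfun).reshape(self.S * self.E, npts)
            eta = eta + self.Zc @ B

        if self.prior_only:
            return logp, theta

        # residual likelihood, standardized by omega
        R = (self.Yc - eta) / ad.exp(log_omega)
        if self.is_2d:
            Kf = ad.square(tau_sigma) * self._corr_f(lam_sigma[0])
            Kh = self._corr_h(lam_sigma[1])
            lf, Qf = ad.eigh(Kf)
            lh, Qh = ad.eigh(Kh)
            evals = (lf.reshape(self.kf, 1) * lh.reshape(1, self.kh)
                     + ad.square(sigma_eps)).reshape(npts)
            R3 = R.reshape(self.N, self.kf, self.kh)
            T = (Qf.T @ R3 @ Qh).reshape(self.N, npts)
            quad = (ad.square(T) / evals.reshape(1, npts)).sum()
            logdet = ad.log(evals).sum()
            loglik = -0.5 * quad - 0.5 * self.N * logdet \
                - log_omega.sum()
        else:
            C = ad.square(tau_sigma) * self._corr_f(lam_sigma[0]) \
                + ad.square(sigma_eps) * self.If
            Lc = ad.cholesky(C)
            Qr = ad.solve_lower(Lc, R.T)
            logdet = 2.0 * ad.log(ad.diag_part(Lc)).sum()
            loglik = -0.5 * ad.square(Qr).sum() - 0.5 * self.N * logdet \
                - log_omega.sum()

        logp = logp + loglik
        return logp, theta

    def logp_grad(self, theta_np):
        """Log posterior and gradient; -inf (divergence) when the point
        is numerically unevaluable (overflow, factorization failure)."""
        try:
            with np.errstate(over="ignore", divide="ignore",
                             invalid="ignore"):
                logp, theta = self(theta_np)
                if not np.isfinite(logp.value):
                    return -np.inf, np.zeros_like(theta_np)
                g = ad.grad(logp, [theta])[0]
            if not np.all(np.isfinite(g)):
                return -np.inf, np.zeros_like(theta_np)
            return float(logp.value), g
        except (np.linalg.LinAlgError, ValueError):
            return -np.inf, np.zeros_like(theta_np)

    # -- decoding draws ---------------------------------------------------
    def decode(self, theta_np):
        """Constrained quantities for one draw (plain numpy mirror of the
        graph above)."""
        lay = self.layout
        sp = self.spec
        n_lam = 2 if self.is_2d else 1
        g = lambda name: theta_np[lay.slices[name]]
        mu, sd = sp.lambda_mu, sp.lambda_sd

        rho = None
        if self.is_2d:
            rho = 1.0 / (1.0 + np.exp(-g("logit_rho")[0]))

        def lam_of(z):
            if not self.is_2d:
                return (np.exp(mu + sd * z[0]),)
            e1, e2 = z
            if rho is not None:
                e2 = rho * e1 + np.sqrt(1 - rho ** 2) * e2
            return (np.exp(mu + sd * e1), np.exp(mu + sd * e2))

        zb = g("z_lam_beta").reshape(self.P, n_lam)
        zg = g("z_lam_gamma").reshape(self.Q, n_lam)
        lam_beta = [lam_of(zb[p]) for p in range(self.P)]
        lam_gamma = [lam_of(zg[q]) for q in range(self.Q)]
        tau_beta = np.exp(g("log_tau_beta"))
        tau_gamma = np.exp(g("log_tau_gamma"))
        lam_b = lam_of(g("z_lam_b")) if self.S else None

        zeta = g("zeta_lam_sigma")
        lam_sigma = []
        for i in range(n_lam):
            pool = [t[i] for t in lam_beta + lam_gamma]
            if lam_b is not None:
                pool.append(lam_b[i])
            lam_sigma.append(min(pool) / (1.0 + np.exp(-zeta[i])))
        lam_sigma = tuple(lam_sigma)
        tau_sigma = np.exp(g("log_tau_sigma")[0])
        sigma_eps = np.exp(g("log_sigma_eps")[0])

        lfreq = np.log(sp.fgrid.centers)
        D2f = -0.5 * (lfreq[:, None] - lfreq[None, :]) ** 2

        def corr_f(lam):
            return np.exp(D2f / lam ** 2) + JITTER_REL * np.eye(self.kf)

        def corr_h(lam):
            ph = sp.pgrid.centers
            S2 = -2.0 * np.sin(0.5 * np.abs(ph[:, None] - ph[None, :])) ** 2
            return np.exp(S2 / lam ** 2) + JITTER_REL * np.eye(self.kh)

        def whiten(til, lams, tau=1.0):
            Lf = np.linalg.cholesky(corr_f(lams[0]))
            if self.is_2d:
                Lh = np.linalg.cholesky(corr_h(lams[1]))
                return tau * (Lf @ til.reshape(self.kf, self.kh)
                              @ Lh.T).ravel()
            return tau * (Lf @ til)

        npts = self.n_points
        bt = g("beta_til").reshape(self.P, npts)
        beta = np.stack([whiten(bt[p], lam_beta[p], tau_beta[p])
                         for p in range(self.P)])
        if self.Q:
            gt = g("gamma_til").reshape(self.Q, npts)
            gamma = np.stack([whiten(gt[q], lam_gamma[q], tau_gamma[q])
                              for q in range(self.Q)])
        else:
            gamma = np.zeros((0, npts))

        b = np.zeros((self.S * self.E, npts))
        sd_b = corr_mat = None
        if self.S:
            sd_b = np.exp(g("log_sd_b"))
            if self.E > 1:
                Lcorr = _lkj_chol_numpy(g("lkj_y"), self.E)
            else:
                Lcorr = np.ones((1, 1))
            corr_mat = Lcorr @ Lcorr.T
            A_b = sd_b[:, None] * Lcorr
            b_til = g("b_til").reshape(self.S, self.E, npts)
            Lbf = np.linalg.cholesky(corr_f(lam_b[0]))
            Lbh = np.linalg.cholesky(corr_h(lam_b[1])) if self.is_2d else None
            for s in range(self.S):
                if self.is_2d:
                    W = np.stack([(Lbf @ b_til[s, e].reshape(self.kf, self.kh)
                                   @ Lbh.T).ravel() for e in range(self.E)])
                else:
                    W = b_til[s] @ Lbf.T
                b[s * self.E:(s + 1) * self.E] = A_b @ W

        hyper = {"tau_beta": tau_beta, "tau_gamma": tau_gamma,
                 "lam_beta": np.array([list(t) for t in lam_beta]),
                 "lam_gamma": np.array([list(t) for t in lam_gamma]),
                 "tau_sigma": tau_sigma, "lam_sigma": np.array(lam_sigma),
                 "sigma_eps": sigma_eps}
        if lam_b is not None:
            hyper["lam_b"] = np.array(lam_b)
            hyper["sd_b"] = sd_b
            hyper["corr_b"] = corr_mat
        if rho is not None:
            hyper["rho"] = rho
        return beta, b, gamma, hyper


def _lkj_chol_numpy(y, E):
    z = np.tanh(y)
    L = np.zeros((E, E))
    idx = 0
    for i in range(E):
        acc = 0.0
        for j in range(i):
            w = np.sqrt(max(1.0 - acc, 1e-15))
            L[i, j] = z[idx] * w
            acc += L[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(max(1.0 - acc, 1e-15))
    return L


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _resolve_offset(spec, Y):
    if isinstance(spec.offset, str):
        if spec.offset == "mean":
            return float(np.mean(Y))
        if spec.offset == "zero":
            return 0.0
        raise ValueError(f"unknown offset policy {spec.offset!r}")
    return np.asarray(spec.offset, float)


def fit_hmc(spec: ModelSpec, dm: DesignMatrices, Y: np.ndarray,
            chains: int = 8, warmup: int = 500, iters: int = 500,
            seed: int = 0, adapt_delta: float = 0.9,
            max_treedepth: int = 10, prior_only: bool = False,
            progress: bool = False) -> PosteriorDraws:
    """Sample the posterior with zero-initialized NUTS chains.

    Returns draws of all effect functions and hyperparameters
    (chains x iters total draws) with convergence diagnostics (split
    R-hat and effective sample size via ArviZ, divergence counts, tree
    depths).
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[1] != spec.n_points:
        raise ValueError(f"responses have {Y.shape[1]} points; spec grid "
                         f"has {spec.n_points}")
    offset = _resolve_offset(spec, Y)
    post = _LogPosterior(spec, dm, Y, offset, prior_only=prior_only)
    theta0 = np.zeros(post.layout.size)
    cfg = NutsConfig(warmup=warmup, samples=iters, adapt_delta=adapt_delta,
                     max_treedepth=max_treedepth)
    seeds = np.random.SeedSequence(seed).spawn(chains)
    all_draws, all_stats = [], []
    for c in range(chains):
        chain_seed = int(seeds[c].generate_state(1)[0] % (2 ** 31))
        draws, stats = nuts_chain(post.logp_grad, theta0, cfg, chain_seed)
        all_draws.append(draws)
        all_stats.append(stats)
        if progress:
            print(f"chain {c + 1}/{chains}: divergences={stats.divergences} "
                  f"stepsize={stats.stepsize:.3g}")

    theta_draws = np.concatenate(all_draws, axis=0)
    n_total = theta_draws.shape[0]
    npts = spec.n_points
    beta = np.empty((n_total, post.P, npts))
    gamma = np.empty((n_total, post.Q, npts))
    b = np.empty((n_total, post.S * post.E, npts))
    hyper_rows = []
    for i in range(n_total):
        bi, bbi, gi, hy = post.decode(theta_draws[i])
        beta[i], b[i], gamma[i] = bi, bbi, gi
        hyper_rows.append(hy)
    hyper = {k: np.stack([h[k] for h in hyper_rows])
             for k in hyper_rows[0]}

    diagnostics = _diagnostics(all_draws, all_stats, post, chains, iters)
    return PosteriorDraws(beta=beta, b=b, gamma=gamma, hyper=hyper,
                          diagnostics=diagnostics, spec=spec, dm=dm,
                          offset=offset)


def _diagnostics(all_draws, all_stats, post, chains, iters):
    import warnings

    div = sum(s.divergences for s in all_stats)
    depth = max((max(s.treedepths[-iters:]) for s in all_stats), default=0)
    diag = {"divergences": int(div), "max_treedepth": int(depth),
            "stepsizes": [float(s.stepsize) for s in all_stats],
            "n_draws": int(chains * iters)}
    # R-hat / ESS on the hyperparameter coordinates (cheap, informative)
    try:
        import arviz as az
        names = [n for n in ("log_tau_sigma", "zeta_lam_sigma",
                             "log_sigma_eps", "log_tau_beta")
                 if n in post.layout.slices]
        sub = np.stack([np.concatenate(
            [d[:, post.layout.slices[n]] for n in names], axis=1)
            for d in all_draws])  # (chain, draw, dim)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(az.convert_to_dataset(sub))
            ess = az.ess(az.convert_to_dataset(sub))
            diag["rhat_max"] = float(np.nanmax(rhat.to_array().values))
            diag["ess_min"] = float(np.nanmin(ess.to_array().values))
    except Exception:  # diagnostics must never fail a fit
        diag["rhat_max"] = float("nan")
        diag["ess_min"] = float("nan")
    return diag


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class GPFunctionalMixedModel:
    """sklearn-style estimator for the GP functional mixed-effects model.

    Parameters
    ----------
    mean_formula, scale_formula : str
        Mixed-model formulas for eta and log omega (see the design module).
    chains, warmup, iter_sampling : int
        Sampler configuration; the reference configuration is 8 chains of
        500 warmup + 500 sampling iterations (4000 posterior draws).
    adapt_delta, max_treedepth : HMC tuning knobs.
    offset : "mean" | "zero" | array
        The eta offset policy; "mean" centers responses at their grand
        mean.

    After ``fit``, ``posterior_`` holds the :class:`PosteriorDraws`,
    ``diagnostics_`` the sampler diagnostics dict.
    """

    def __init__(self, mean_formula: str = "group*region*meal"
                                           " + (region*meal|subject)",
                 scale_formula: str = "group*region*meal + nchan",
                 chains: int = 8, warmup: int = 500,
                 iter_sampling: int = 500, adapt_delta: float = 0.9,
                 max_treedepth: int = 10, offset="mean"):
        self.mean_formula = mean_formula
        self.scale_formula = scale_formula
        self.chains = chains
        self.warmup = warmup
        self.iter_sampling = iter_sampling
        self.adapt_delta = adapt_delta
        self.max_treedepth = max_treedepth
        self.offset = offset

    _param_names = ("mean_formula", "scale_formula", "chains", "warmup",
                    "iter_sampling", "adapt_delta", "max_treedepth",
                    "offset")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, responses, obs=None, seed: int = 0):
        """Fit to a list of Spectrum1D / Spectrum2D (or a response matrix
        plus explicit grids via ``(Y, fgrid[, pgrid])``)."""
        Y, fgrid, pgrid, obs = _gather_responses(responses, obs)
        self.dm_ = build_design_matrices(obs, self.mean_formula,
                                         self.scale_formula)
        self.spec_ = ModelSpec(fgrid=fgrid, pgrid=pgrid, offset=self.offset)
        self.posterior_ = fit_hmc(
            self.spec_, self.dm_, Y, chains=self.chains, warmup=self.warmup,
            iters=self.iter_sampling, seed=seed,
            adapt_delta=self.adapt_delta, max_treedepth=self.max_treedepth)
        self.diagnostics_ = self.posterior_.diagnostics
        return self


def _gather_responses(responses, obs):
    import pandas as pd

    if isinstance(responses, tuple):
        Y = np.atleast_2d(np.asarray(responses[0], float))
        fgrid = responses[1]
        pgrid = responses[2] if len(responses) > 2 else None
        if obs is None:
            raise ValueError("an observation table is required")
        return Y, fgrid, pgrid, obs
    responses = list(responses)
    if not responses:
        raise ValueError("no responses given")
    first = responses[0]
    if isinstance(first, Spectrum1D):
        fgrid, pgrid = first.grid, None
        Y = np.stack([s.y for s in responses])
    elif isinstance(first, Spectrum2D):
        fgrid, pgrid = first.fgrid, first.pgrid
        Y = np.stack([s.y.ravel() for s in responses])
    else:
        raise TypeError("responses must be Spectrum1D or Spectrum2D")
    if obs is None:
        obs = pd.DataFrame([s.meta for s in responses])
    return Y, fgrid, pgrid, obs
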