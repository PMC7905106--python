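"""Adaptive Hamiltonian Monte Carlo (No-U-Turn sampler).

A self-contained NUTS implementation in the style of Hoffman & Gelman
(2014, Algorithm 6) with Stan-like warmup: dual-averaging step-size
adaptation toward a target acceptance statistic (``adapt_delta``) and
windowed estimation of a diagonal mass matrix.  The model supplies a
single callback returning the log posterior density and its gradient on
the unconstrained scale.

Used at modest dimension (hundreds of parameters) where a pure-numpy
leapfrog is fast enough; trajectory length is capped by ``max_treedepth``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NutsConfig", "ChainStats", "nuts_chain"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsConfig:
    warmup: int = 500
    samples: int = 500
    adapt_delta: float = 0.9
    max_treedepth: int = 10
    init_stepsize: float = 0.1
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75


@dataclass
class ChainStats:
    divergences: int = 0            # sampling phase only
    divergences_warmup: int = 0
    treedepths: list = field(default_factory=list)
    stepsize: float = 0.0
    accept_stats: list = field(default_factory=list)
    inv_mass: np.ndarray | None = None


class _Tree:
    __slots__ = ("theta_m", "r_m", "grad_m", "theta_p", "r_p", "grad_p",
                 "theta_prop", "n", "stop", "alpha", "n_alpha")


def _kinetic(r, inv_mass):
    return 0.5 * np.dot(r * inv_mass, r)


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * r1
    lp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, lp1, grad1


def _uturn(theta_p, theta_m, r_p, r_m, inv_mass):
    d = theta_p - theta_m
    return (np.dot(d, inv_mass * r_m) < 0) or (np.dot(d, inv_mass * r_p) < 0)


def _build_tree(logp_grad, theta, r, grad, logu, v, j, eps, H0, inv_mass,
                rng, stats):
    tree = _Tree()
    if j == 0:
        theta1, r1, lp1, grad1 = _leapfrog(logp_grad, theta, r, grad,
                                           v * eps, inv_mass)
        H = lp1 - _kinetic(r1, inv_mass)
        diverged = (not np.isfinite(H)) or (logu > H + _DIVERGENCE_THRESHOLD)
        if diverged:
            stats.divergences += 1
        tree.theta_m = tree.theta_p = theta1
        tree.r_m = tree.r_p = r1
        tree.grad_m = tree.grad_p = grad1
        tree.theta_prop = theta1
        tree.n = int(logu <= H)
        tree.stop = diverged
        tree.alpha = min(1.0, np.exp(min(H - H0, 0.0))) if np.isfinite(H) \
            else 0.0
        tree.n_alpha = 1
        return tree

    left = _build_tree(logp_grad, theta, r, grad, logu, v, j - 1, eps, H0,
                       inv_mass, rng, stats)
    tree = left
    if not tree.stop:
        if v == -1:
            sub = _build_tree(logp_grad, tree.theta_m, tree.r_m, tree.grad_m,
                              logu, v, j - 1, eps, H0, inv_mass, rng, stats)
            tree.theta_m, tree.r_m, tree.grad_m = (sub.theta_m, sub.r_m,
                                                   sub.grad_m)
        else:
            sub = _build_tree(logp_grad, tree.theta_p, tree.r_p, tree.grad_p,
                              logu, v, j - 1, eps, H0, inv_mass, rng, stats)
            tree.theta_p, tree.r_p, tree.grad_p = (sub.theta_p, sub.r_p,
                                                   sub.grad_p)
        total = tree.n + sub.n
        if sub.n > 0 and rng.uniform() < sub.n / total:
            tree.theta_prop = sub.theta_prop
        tree.alpha += sub.alpha
        tree.n_alpha += sub.n_alpha
        tree.n = total
        tree.stop = (sub.stop or _uturn(tree.theta_p, tree.theta_m,
                                        tree.r_p, tree.r_m, inv_mass))
    return tree


def _find_initial_stepsize(logp_grad, theta, inv_mass, rng, eps0=1.0):
    """Heuristic stepsize init: double/halve until acceptance crosses 1/2."""
    lp, grad = logp_grad(theta)
    r = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    H0 = lp - _kinetic(r, inv_mass)
    eps = eps0
    _, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    H1 = lp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(H1):
        H1 = -np.inf
    a = 1.0 if H1 - H0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** a
        _, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        H1 = lp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(H1):
            H1 = -np.inf
        if a * (H1 - H0) <= a * np.log(0.5):
            break
    return eps


def _adapt_windows(warmup):
    """Stan-style warmup schedule: (init buffer, [covariance-window ends],
    terminal buffer start)."""
    init_buf, term_buf, base = 75, 50, 25
    if warmup < 20:
        return warmup, [], warmup
    if init_buf + term_buf + base > warmup:
        init_buf = int(0.15 * warmup)
        term_buf = int(0.1 * warmup)
        base = warmup - init_buf - term_buf
        return init_buf, [init_buf + base], init_buf + base
    ends, start, size = [], init_buf, base
    while start + size < warmup - term_buf:
        nxt = start + size
        if nxt + 2 * size >= warmup - term_buf:
            nxt = warmup - term_buf
        ends.append(nxt)
        start, size = nxt, size * 2
    return init_buf, ends, warmup - term_buf


def nuts_chain(logp_grad, theta0, config: NutsConfig, seed: int):
    """Run one NUTS chain; returns (draws, ChainStats).

    ``logp_grad(theta) -> (logp, grad)`` on the unconstrained scale;
    ``theta0`` is the initial point (zeros, by convention, for model fits).
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta0, float).copy()
    d = len(theta)
    inv_mass = np.ones(d)
    stats = ChainStats()

    eps = _find_initial_stepsize(logp_grad, theta, inv_mass, rng,
                                 config.init_stepsize)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0

    init_buf, win_ends, term_start = _adapt_windows(config.warmup)
    welford_n, welford_mean, welford_m2 = 0, np.zeros(d), np.zeros(d)

    lp, grad = logp_grad(theta)
    draws = np.empty((config.samples, d))
    total = config.warmup + config.samples

    for it in range(total):
        warming = it < config.warmup
        r0 = rng.standard_normal(d) / np.sqrt(inv_mass)
        H0 = lp - _kinetic(r0, inv_mass)
        logu = H0 + np.log(rng.uniform())
        theta_m = theta_p = theta
        r_m = r_p = r0
        grad_m = grad_p = grad
        theta_new = theta
        n, j, stop = 1, 0, False
        alpha_sum, n_alpha = 0.0, 0
        while not stop and j < config.max_treedepth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                sub = _build_tree(logp_grad, theta_m, r_m, grad_m, logu, v,
                                  j, eps, H0, inv_mass, rng, stats)
                theta_m, r_m, grad_m = sub.theta_m, sub.r_m, sub.grad_m
            else:
                sub = _build_tree(logp_grad, theta_p, r_p, grad_p, logu, v,
                                  j, eps, H0, inv_mass, rng, stats)
                theta_p, r_p, grad_p = sub.theta_p, sub.r_p, sub.grad_p
            if not sub.stop and sub.n > 0 \
                    and rng.uniform() < min(1.0, sub.n / n):
                theta_new = sub.theta_prop
            n += sub.n
            alpha_sum += sub.alpha
            n_alpha += sub.n_alpha
            stop = sub.stop or _uturn(theta_p, theta_m, r_p, r_m, inv_mass)
            j += 1

        theta = theta_new
        lp, grad = logp_grad(theta)
        accept_stat = alpha_sum / max(n_alpha, 1)
        stats.treedepths.append(j)
        stats.accept_stats.append(accept_stat)

        if warming:
            m_adapt += 1
            h_bar = ((1.0 - 1.0 / (m_adapt + config.t0)) * h_bar
                     + (config.adapt_delta - accept_stat)
                     / (m_adapt + config.t0))
            log_eps = mu - np.sqrt(m_adapt) / config.gamma * h_bar
            w = m_adapt ** -config.kappa
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = np.exp(log_eps)

            if init_buf <= it < term_start:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
                if (it + 1) in win_ends and welford_n > 2:
                    var = welford_m2 / (welford_n - 1)
                    # regularize toward unit scale as Stan does
                    var = (welford_n / (welford_n + 5.0)) * var \
                        + 1e-3 * (5.0 / (welford_n + 5.0))
                    inv_mass = np.maximum(var, 1e-10)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    eps = _find_initial_stepsize(logp_grad, theta, inv_mass,
                                                 rng, eps)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
            if it == config.warmup - 1:
                eps = np.exp(log_eps_bar)
                stats.divergences_warmup = stats.divergences
                stats.divergences = 0
        else:
            draws[it - config.warmup] = theta

    stats.stepsize = eps
    stats.inv_mass = inv_mass
    return draws, stats
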