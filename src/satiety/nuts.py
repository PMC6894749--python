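"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC kernel (the slice-sampling NUTS variant
of Hoffman & Gelman, with the dynamic termination criterion evaluated in the
metric induced by a diagonal mass matrix).  The caller supplies
``logp_and_grad(w) -> (float, ndarray)``; everything else — warmup schedule,
step-size adaptation targeting a given acceptance statistic, windowed
estimation of the diagonal metric from warmup draws, divergence detection —
is handled here.

This is deliberately a small, well-tested kernel rather than a framework:
the hierarchical feeding model supplies analytic gradients, so no autodiff
machinery is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NUTSResult", "nuts_sample"]

_MAX_DELTA_H = 1000.0  # energy error beyond which a trajectory is divergent


@dataclass
class NUTSResult:
    draws: np.ndarray          # (n_draws, dim)
    logp: np.ndarray           # (n_draws,)
    divergences: int
    accept_stat: float         # mean acceptance statistic over kept draws
    step_size: float
    inv_mass: np.ndarray       # diagonal of the inverse mass matrix
    treedepths: np.ndarray


def _leapfrog(logp_and_grad, w, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    w = w + eps * inv_mass * p
    logp, grad = logp_and_grad(w)
    p = p + 0.5 * eps * grad
    return w, p, grad, logp


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


def _find_reasonable_eps(logp_and_grad, w0, rng, inv_mass):
    eps = 1.0
    logp0, grad0 = logp_and_grad(w0)
    p0 = rng.normal(size=w0.shape) / np.sqrt(inv_mass)
    h0 = logp0 - _kinetic(p0, inv_mass)
    w, p, grad, logp = _leapfrog(logp_and_grad, w0, p0, grad0, eps, inv_mass)
    h = logp - _kinetic(p, inv_mass)
    if not np.isfinite(h):
        h = -np.inf
    direction = 1.0 if (h - h0) > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0**direction
        w, p, grad, logp = _leapfrog(logp_and_grad, w0, p0, grad0, eps, inv_mass)
        h = logp - _kinetic(p, inv_mass)
        if not np.isfinite(h):
            h = -np.inf
        if direction * (h - h0) <= direction * np.log(0.5):
            break
    return eps


class _Welford:
    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self):
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularise as in standard practice for metric estimation
        return (self.n / (self.n + 5.0)) * var + 1e-3 * (5.0 / (self.n + 5.0))


def nuts_sample(logp_and_grad: Callable, w0: np.ndarray, n_warmup: int,
                n_draws: int, rng: np.random.Generator,
                max_treedepth: int = 10, target_accept: float = 0.8) -> NUTSResult:
    """Run one NUTS chain; warmup draws are discarded."""
    w = np.asarray(w0, dtype=float).copy()
    dim = w.size
    inv_mass = np.ones(dim)
    logp, grad = logp_and_grad(w)
    if not np.isfinite(logp):
        raise ValueError("log-probability is not finite at the initial point")

    eps = _find_reasonable_eps(logp_and_grad, w, rng, inv_mass)
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = np.log(eps), 0.0
    m_da = 0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    # warmup: initial fast phase, expanding metric windows, final fast phase
    init_fast = max(int(0.15 * n_warmup), 10) if n_warmup else 0
    term_fast = max(int(0.10 * n_warmup), 10) if n_warmup else 0
    window_end = []
    if n_warmup > init_fast + term_fast + 20:
        wsize = 25
        pos = init_fast
        while pos + wsize < n_warmup - term_fast:
            pos += wsize
            window_end.append(min(pos, n_warmup - term_fast))
            wsize *= 2
        if not window_end or window_end[-1] != n_warmup - term_fast:
            window_end.append(n_warmup - term_fast)
    welford = _Welford(dim)

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    depths = np.empty(n_draws, dtype=int)
    accept_sum = 0.0
    divergences = 0

    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        p0 = rng.normal(size=dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(p0, inv_mass)
        log_u = np.log(rng.random()) + h0

        w_minus = w_plus = w
        p_minus = p_plus = p0
        g_minus = g_plus = grad
        w_prop, logp_prop, grad_prop = w, logp, grad
        depth, n_valid, keep_going = 0, 1, True
        sum_alpha, n_alpha = 0.0, 0
        diverged = False

        while keep_going and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                (_, _, _, w_plus, p_plus, g_plus, w1, lp1, g1, n1, s1,
                 a1, na1, div1) = _build_tree(
                    logp_and_grad, w_plus, p_plus, g_plus, log_u, direction,
                    depth, eps, inv_mass, h0, rng)
            else:
                (w_minus, p_minus, g_minus, _, _, _, w1, lp1, g1, n1, s1,
                 a1, na1, div1) = _build_tree(
                    logp_and_grad, w_minus, p_minus, g_minus, log_u, direction,
                    depth, eps, inv_mass, h0, rng)
            diverged = diverged or div1
            if s1 and n1 > 0 and rng.random() < n1 / max(n_valid, 1):
                w_prop, logp_prop, grad_prop = w1, lp1, g1
            n_valid += n1
            sum_alpha += a1
            n_alpha += na1
            dw = w_plus - w_minus
            keep_going = (s1
                          and np.dot(dw, inv_mass * p_minus) >= 0
                          and np.dot(dw, inv_mass * p_plus) >= 0)
            depth += 1

        w, logp, grad = w_prop, logp_prop, grad_prop
        alpha_mean = sum_alpha / max(n_alpha, 1)

        if warming:
            # dual averaging (local counter restarts with each metric window)
            m_da += 1
            h_bar = (1 - 1 / (m_da + t0_da)) * h_bar \
                + (target_accept - alpha_mean) / (m_da + t0_da)
            log_eps = mu_da - np.sqrt(m_da) / gamma_da * h_bar
            eta = m_da**-kappa_da
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            in_window = it >= init_fast and it < n_warmup - term_fast
            if in_window:
                welford.update(w)
            if window_end and it + 1 == window_end[0]:
                if welford.n >= 10:
                    inv_mass = welford.variance()
                    # restart dual averaging from the current adapted step
                    eps = float(np.exp(log_eps_bar))
                    mu_da = np.log(10.0 * eps)
                    log_eps_bar, h_bar = np.log(eps), 0.0
                    m_da = 0
                welford = _Welford(dim)
                window_end.pop(0)
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            j = it - n_warmup
            draws[j] = w
            logps[j] = logp
            depths[j] = depth
            accept_sum += alpha_mean
            if diverged:
                divergences += 1

    return NUTSResult(
        draws=draws, logp=logps, divergences=divergences,
        accept_stat=accept_sum / max(n_draws, 1), step_size=eps,
        inv_mass=inv_mass, treedepths=depths)


def _build_tree(logp_and_grad, w, p, grad, log_u, direction, depth, eps,
                inv_mass, h0, rng):
    """Recursive doubling; returns the subtree edges, a proposal and stats."""
    if depth == 0:
        w1, p1, g1, lp1 = _leapfrog(logp_and_grad, w, p, grad, direction * eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
        div = (h0 - h1) > _MAX_DELTA_H or not np.isfinite(h1)
        n1 = int(log_u <= h1)
        s1 = (not div) and (log_u < h1 + _MAX_DELTA_H)
        alpha = float(np.exp(min(0.0, h1 - h0))) if np.isfinite(h1) else 0.0
        return (w1, p1, g1, w1, p1, g1, w1, lp1, g1, n1, s1, alpha, 1, div)

    (wm, pm, gm, wp, pp, gp, w1, lp1, g1, n1, s1, a1, na1, div1) = _build_tree(
        logp_and_grad, w, p, grad, log_u, direction, depth - 1, eps, inv_mass, h0, rng)
    if s1:
        if direction == 1:
            (_, _, _, wp, pp, gp, w2, lp2, g2, n2, s2, a2, na2, div2) = _build_tree(
                logp_and_grad, wp, pp, gp, log_u, direction, depth - 1, eps,
                inv_mass, h0, rng)
        else:
            (wm, pm, gm, _, _, _, w2, lp2, g2, n2, s2, a2, na2, div2) = _build_tree(
                logp_and_grad, wm, pm, gm, log_u, direction, depth - 1, eps,
                inv_mass, h0, rng)
        if n2 > 0 and rng.random() < n2 / max(n1 + n2, 1):
            w1, lp1, g1 = w2, lp2, g2
        dw = wp - wm
        s1 = (s2
              and np.dot(dw, inv_mass * pm) >= 0
              and np.dot(dw, inv_mass * pp) >= 0)
        n1 += n2
        a1 += a2
        na1 += na2
        div1 = div1 or div2
    return (wm, pm, gm, wp, pp, gp, w1, lp1, g1, n1, s1, a1, na1, div1)
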