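"""Exact log-likelihood of an observed event sequence.

The likelihood factorises over events:

* bout duration            Exponential(lambda_F) density (survival if censored)
* per-bout feeding rate    Normal(mu_F, sigma_F) truncated below at 0
* post-bout routing        sigmoid(T1 (x - T2)) for meal termination (-> L),
                           its complement for a short pause (-> S), evaluated
                           at the bout-end fullness
* short pause duration     Exponential(lambda_S) density / survival
* intermeal interval       time-varying-hazard density
                           lambda_L(x(t)) exp(-Lambda(t)),
                           lambda_L(x) = 1/(L1 + L2 x),
                           along the emptying trajectory from the fullness at
                           meal termination; survival exp(-Lambda(t)) for the
                           window-censored final interval.

Fullness at every event boundary is recomputed from the observed bouts
(never trusted from file metadata).  All terms have analytic derivatives in
the eight behavioural parameters, which this module exposes for use by
gradient-based samplers and optimisers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

from .gut import GutModel, empty_fullness, empty_fullness_vec, imi_hazard_terms
from .params import LN10, LOG10_MASK, ModelParams, N_PARAMS, back_transform
from .simulate import FeedingSequence

__all__ = [
    "SequenceStats",
    "imi_logpdf",
    "imi_logsurvival",
    "sequence_loglik",
    "sequence_loglik_and_grad",
    "per_event_loglik",
    "fit_mle",
]

_SQ2PI = np.log(2.0 * np.pi) / 2.0


def imi_logsurvival(t, x0, params: ModelParams, gut: GutModel):
    """log P(intermeal interval > t | fullness x0 at meal termination) = -Lambda(t)."""
    lam, _, _ = imi_hazard_terms(x0, t, params.L1, params.L2, gut)
    return -lam

def imi_logpdf(t, x0, params: ModelParams, gut: GutModel):
    """Log-density of the intermeal interval started at fullness ``x0``.

    ``log lambda_L(x(t)) - Lambda(t)``; integrates to one over t in (0, inf).
    """
    if np.any(np.asarray(t) <= 0):
        raise ValueError("t must be > 0")
    x_t = empty_fullness(x0, t, gut) if np.ndim(t) == 0 else np.array(
        [empty_fullness(x0, ti, gut) for ti in np.atleast_1d(t)])
    lam, _, _ = imi_hazard_terms(x0, t, params.L1, params.L2, gut)
    return -np.log(params.L1 + params.L2 * x_t) - lam


@dataclass
class SequenceStats:
    """Sufficient event-level arrays for likelihood evaluation.

    Built once per (sequence, gut model); the behavioural parameters enter
    only through the likelihood, so repeated evaluations (MCMC, optimisers)
    reuse these arrays.
    """

    bout_durations: np.ndarray      # complete bouts
    cens_bout_durations: np.ndarray
    rates: np.ndarray               # all bouts (rate observed even if censored)
    routing_x: np.ndarray           # bout-end fullness where routing observed
    routing_to_L: np.ndarray        # bool
    s_durations: np.ndarray
    cens_s_durations: np.ndarray
    l_durations: np.ndarray
    l_x0: np.ndarray
    cens_l_durations: np.ndarray
    cens_l_x0: np.ndarray
    n_events: int

    @classmethod
    def from_sequence(cls, seq: FeedingSequence, gut: GutModel,
                      x_init: Optional[float] = None) -> "SequenceStats":
        if x_init is None:
            x_init = seq.x_init
        for p in seq.pauses():
            if p.pause_class not in ("S", "L"):
                raise ValueError(
                    "unresolved pause classes; run satiety.io.label_meals first")
        bd, cbd, rates = [], [], []
        rx, rl = [], []
        sd, csd = [], []
        ld, lx, cld, clx = [], [], [], []
        x = float(x_init)
        t = seq.window[0]
        events = seq.events
        for i, ev in enumerate(events):
            if ev.start > t + 1e-12:  # unrecorded gap: emptying only
                x = empty_fullness(x, ev.start - t, gut)
            if ev.kind == "bout":
                if ev.censored:
                    cbd.append(ev.duration)
                else:
                    bd.append(ev.duration)
                if ev.duration > 0:
                    rates.append(ev.amount / ev.duration)
                if getattr(ev, "fills_gut", True):
                    x += ev.amount
                if not ev.censored:
                    nxt = events[i + 1] if i + 1 < len(events) else None
                    if nxt is not None and nxt.kind == "pause":
                        rx.append(x)
                        rl.append(nxt.pause_class == "L")
            else:
                if ev.pause_class == "S":
                    (csd if ev.censored else sd).append(ev.duration)
                else:
                    if ev.censored:
                        cld.append(ev.duration)
                        clx.append(x)
                    else:
                        ld.append(ev.duration)
                        lx.append(x)
                x = empty_fullness(x, ev.duration, gut)
            t = ev.end
        return cls(
            bout_durations=np.asarray(bd), cens_bout_durations=np.asarray(cbd),
            rates=np.asarray(rates),
            routing_x=np.asarray(rx), routing_to_L=np.asarray(rl, dtype=bool),
            s_durations=np.asarray(sd), cens_s_durations=np.asarray(csd),
            l_durations=np.asarray(ld), l_x0=np.asarray(lx),
            cens_l_durations=np.asarray(cld), cens_l_x0=np.asarray(clx),
            n_events=len(events))

    @property
    def n_meals(self) -> int:
        return int(np.sum(self.routing_to_L))


def _truncnorm_terms(rates: np.ndarray, mu: float, sigma: float):
    """(loglik, d/dmu, d/dsigma) for rates ~ N(mu, sigma) truncated at 0."""
    n = len(rates)
    if n == 0:
        return 0.0, 0.0, 0.0
    z = (rates - mu) / sigma
    alpha = mu / sigma
    log_phi_a = -0.5 * alpha**2 - _SQ2PI
    log_Phi_a = log_ndtr(alpha)
    ratio = np.exp(log_phi_a - log_Phi_a)  # hazard ratio phi/Phi at alpha
    ll = float(np.sum(-np.log(sigma) - 0.5 * z**2 - _SQ2PI) - n * log_Phi_a)
    dmu = float(np.sum(z) / sigma - n * ratio / sigma)
    dsig = float(np.sum(z**2 - 1.0) / sigma + n * alpha * ratio / sigma)
    return ll, dmu, dsig


def sequence_loglik_and_grad(stats: SequenceStats, params: ModelParams | np.ndarray,
                             gut: GutModel):
    """(log-likelihood, gradient) in the eight natural-scale parameters."""
    th = params.as_array() if isinstance(params, ModelParams) else np.asarray(params, float)
    lF, muF, sigF, lS, T1, T2, L1, L2 = th
    ll = 0.0
    g = np.zeros(N_PARAMS)

    # bout durations
    n_b = len(stats.bout_durations)
    sum_d = stats.bout_durations.sum() + stats.cens_bout_durations.sum()
    ll += n_b * np.log(lF) - lF * sum_d
    g[0] += n_b / lF - sum_d

    # per-bout rates (truncated normal)
    tll, dmu, dsig = _truncnorm_terms(stats.rates, muF, sigF)
    ll += tll
    g[1] += dmu
    g[2] += dsig

    # routing (meal termination kernel)
    if len(stats.routing_x):
        eta = T1 * (stats.routing_x - T2)
        # log sigmoid(eta) if to_L else log sigmoid(-eta), stably
        sgn = np.where(stats.routing_to_L, 1.0, -1.0)
        ll += float(np.sum(-np.logaddexp(0.0, -sgn * eta)))
        p = 1.0 / (1.0 + np.exp(-eta))
        deta = np.where(stats.routing_to_L, 1.0 - p, -p)
        g[4] += float(np.sum(deta * (stats.routing_x - T2)))
        g[5] += float(np.sum(deta * (-T1)))

    # short pauses
    n_s = len(stats.s_durations)
    sum_s = stats.s_durations.sum() + stats.cens_s_durations.sum()
    ll += n_s * np.log(lS) - lS * sum_s
    g[3] += n_s / lS - sum_s

    # complete intermeal intervals
    if len(stats.l_durations):
        lam, dA, dB = imi_hazard_terms(stats.l_x0, stats.l_durations, L1, L2, gut)
        x_t = empty_fullness_vec(stats.l_x0, stats.l_durations, gut)
        denom = L1 + L2 * x_t
        ll += float(np.sum(-np.log(denom) - lam))
        g[6] += float(np.sum(-1.0 / denom - dA))
        g[7] += float(np.sum(-x_t / denom - dB))

    # censored intermeal intervals
    if len(stats.cens_l_durations):
        lam, dA, dB = imi_hazard_terms(
            stats.cens_l_x0, stats.cens_l_durations, L1, L2, gut)
        ll += float(np.sum(-lam))
        g[6] += float(np.sum(-dA))
        g[7] += float(np.sum(-dB))

    return float(ll), g


def sequence_loglik(seq_or_stats, params: ModelParams, gut: GutModel,
                    x_init: Optional[float] = None) -> float:
    """Log-likelihood of a sequence (or precomputed stats) under ``params``."""
    stats = (seq_or_stats if isinstance(seq_or_stats, SequenceStats)
             else SequenceStats.from_sequence(seq_or_stats, gut, x_init))
    ll, _ = sequence_loglik_and_grad(stats, params, gut)
    return ll


def per_event_loglik(seq: FeedingSequence, params: ModelParams, gut: GutModel,
                     x_init: Optional[float] = None) -> pd.DataFrame:
    """Per-event log-likelihood breakdown (debugging/export aid)."""
    if x_init is None:
        x_init = seq.x_init
    rows = []
    x = float(x_init)
    t = seq.window[0]
    events = seq.events
    for i, ev in enumerate(events):
        if ev.start > t + 1e-12:
            x = empty_fullness(x, ev.start - t, gut)
        terms = {}
        if ev.kind == "bout":
            terms["duration"] = (-params.lambda_F * ev.duration
                                 + (0.0 if ev.censored else np.log(params.lambda_F)))
            if ev.duration > 0:
                tll, _, _ = _truncnorm_terms(
                    np.array([ev.amount / ev.duration]), params.mu_F, params.sigma_F)
                terms["rate"] = tll
            if getattr(ev, "fills_gut", True):
                x += ev.amount
            if not ev.censored and i + 1 < len(events) and events[i + 1].kind == "pause":
                to_L = events[i + 1].pause_class == "L"
                eta = params.T1 * (x - params.T2)
                terms["routing"] = float(-np.logaddexp(0.0, -eta if to_L else eta))
        else:
            if ev.pause_class == "S":
                terms["duration"] = (-params.lambda_S * ev.duration
                                     + (0.0 if ev.censored else np.log(params.lambda_S)))
            else:
                if ev.censored:
                    terms["duration"] = float(imi_logsurvival(ev.duration, x, params, gut))
                else:
                    terms["duration"] = float(imi_logpdf(ev.duration, x, params, gut))
            x = empty_fullness(x, ev.duration, gut)
        t = ev.end
        rows.append({"event": i, "kind": ev.kind, "pause_class": ev.pause_class,
                     "censored": ev.censored,
                     **{f"loglik_{k}": v for k, v in terms.items()},
                     "loglik_total": sum(terms.values())})
    return pd.DataFrame(rows)


def fit_mle(data, gut: GutModel, init: Optional[ModelParams] = None,
            x_init: Optional[float] = None):
    """Maximum-likelihood fit of the eight behavioural parameters.

    ``data`` is one sequence/stats or an iterable of them (pooled fit).
    Optimises on the inference scale (log10 for positive parameters) with
    the analytic gradient.  Returns (ModelParams, OptimizeResult).
    """
    if isinstance(data, (FeedingSequence, SequenceStats)):
        data = [data]
    stats = [d if isinstance(d, SequenceStats)
             else SequenceStats.from_sequence(d, gut, x_init) for d in data]
    if init is None:
        init = _moment_init(stats)
    w0 = init.to_transformed()

    def objective(w):
        th = back_transform(w)
        ll = 0.0
        g = np.zeros(N_PARAMS)
        for st in stats:
            lli, gi = sequence_loglik_and_grad(st, th, gut)
            ll += lli
            g += gi
        # chain rule to the transformed scale
        g_t = g.copy()
        g_t[LOG10_MASK] = g[LOG10_MASK] * th[LOG10_MASK] * LN10
        return -ll, -g_t

    res = minimize(objective, w0, jac=True, method="L-BFGS-B")
    return ModelParams.from_transformed(res.x), res


def _moment_init(stats: Iterable[SequenceStats]) -> ModelParams:
    """Crude moment-based starting point for the optimiser."""
    bd = np.concatenate([s.bout_durations for s in stats] or [np.empty(0)])
    rates = np.concatenate([s.rates for s in stats] or [np.empty(0)])
    sd = np.concatenate([s.s_durations for s in stats] or [np.empty(0)])
    ld = np.concatenate([s.l_durations for s in stats] or [np.empty(0)])
    rx = np.concatenate([s.routing_x for s in stats] or [np.empty(0)])
    lam_F = 1.0 / max(bd.mean(), 1e-6) if len(bd) else 1e-2
    mu = rates.mean() if len(rates) else 1e-3
    sig = max(rates.std(), 0.1 * mu) if len(rates) else 0.3 * mu
    lam_S = 1.0 / max(sd.mean(), 1e-6) if len(sd) else 1e-2
    L1 = max(0.5 * ld.mean(), 10.0) if len(ld) else 1e3
    L2 = L1 / max(rx.mean(), 0.1) if len(rx) else L1
    T2 = rx.mean() if len(rx) else 1.0
    T1 = 2.0 / max(rx.std(), 0.1) if len(rx) > 1 else 1.0
    return ModelParams(lam_F, mu, sig, lam_S, T1, T2, L1, L2)


# ---------------------------------------------------------------------------
# pooled multi-individual evaluation (hot path for hierarchical MCMC)
# ---------------------------------------------------------------------------

@dataclass
class PooledStats:
    """Event arrays of several individuals concatenated with index arrays.

    Evaluating J individuals' likelihoods one by one costs J times the
    fixed numpy call overhead; concatenating the event arrays and using
    segmented sums (bincount) makes the cost nearly independent of J.
    Restricted to the sqrt emptying law, whose hazard terms broadcast over
    per-event parameter values.
    """

    n_individuals: int
    bout_d: np.ndarray
    bout_cens: np.ndarray
    bout_idx: np.ndarray
    rates: np.ndarray
    rate_idx: np.ndarray
    rx: np.ndarray
    r_to_L: np.ndarray
    r_idx: np.ndarray
    s_d: np.ndarray
    s_cens: np.ndarray
    s_idx: np.ndarray
    l_d: np.ndarray
    l_x0: np.ndarray
    l_cens: np.ndarray
    l_idx: np.ndarray

    @classmethod
    def from_stats(cls, stats_per_ind) -> "PooledStats":
        """``stats_per_ind``: list over individuals of lists of SequenceStats."""
        J = len(stats_per_ind)
        bout_d, bout_cens, bout_idx = [], [], []
        rates, rate_idx = [], []
        rx, r_to_L, r_idx = [], [], []
        s_d, s_cens, s_idx = [], [], []
        l_d, l_x0, l_cens, l_idx = [], [], [], []
        for j, st_list in enumerate(stats_per_ind):
            for st in st_list:
                for arr, cens in ((st.bout_durations, False),
                                  (st.cens_bout_durations, True)):
                    bout_d.append(arr)
                    bout_cens.append(np.full(len(arr), cens))
                    bout_idx.append(np.full(len(arr), j, dtype=np.intp))
                rates.append(st.rates)
                rate_idx.append(np.full(len(st.rates), j, dtype=np.intp))
                rx.append(st.routing_x)
                r_to_L.append(st.routing_to_L)
                r_idx.append(np.full(len(st.routing_x), j, dtype=np.intp))
                for arr, cens in ((st.s_durations, False),
                                  (st.cens_s_durations, True)):
                    s_d.append(arr)
                    s_cens.append(np.full(len(arr), cens))
                    s_idx.append(np.full(len(arr), j, dtype=np.intp))
                for darr, xarr, cens in ((st.l_durations, st.l_x0, False),
                                         (st.cens_l_durations, st.cens_l_x0, True)):
                    l_d.append(darr)
                    l_x0.append(xarr)
                    l_cens.append(np.full(len(darr), cens))
                    l_idx.append(np.full(len(darr), j, dtype=np.intp))

        def cat(parts, dtype=float):
            return (np.concatenate(parts).astype(dtype) if parts
                    else np.empty(0, dtype=dtype))

        return cls(
            n_individuals=J,
            bout_d=cat(bout_d), bout_cens=cat(bout_cens, bool),
            bout_idx=cat(bout_idx, np.intp),
            rates=cat(rates), rate_idx=cat(rate_idx, np.intp),
            rx=cat(rx), r_to_L=cat(r_to_L, bool), r_idx=cat(r_idx, np.intp),
            s_d=cat(s_d), s_cens=cat(s_cens, bool), s_idx=cat(s_idx, np.intp),
            l_d=cat(l_d), l_x0=cat(l_x0), l_cens=cat(l_cens, bool),
            l_idx=cat(l_idx, np.intp))


def pooled_loglik_and_grad(pool: PooledStats, theta: np.ndarray, gut: GutModel):
    """Total log-likelihood and per-individual gradient matrix (J, 8).

    ``theta`` is the (J, 8) natural-scale parameter matrix.  Requires the
    sqrt emptying law (closed-form hazard terms).
    """
    from .gut import sqrt_hazard_terms_arr

    if gut.law != "sqrt":
        raise ValueError("pooled likelihood requires the sqrt emptying law")
    J = pool.n_individuals
    g = np.zeros((J, N_PARAMS))
    ll = 0.0

    def seg(idx, w, J=J):
        return np.bincount(idx, weights=w, minlength=J)

    # bout durations
    if len(pool.bout_d):
        lF = theta[pool.bout_idx, 0]
        obs = ~pool.bout_cens
        ll += float(np.sum(np.log(lF[obs])) - np.sum(lF * pool.bout_d))
        g[:, 0] += seg(pool.bout_idx[obs], 1.0 / lF[obs]) - seg(pool.bout_idx, pool.bout_d)

    # rates (truncated normal)
    if len(pool.rates):
        mu = theta[pool.rate_idx, 1]
        sig = theta[pool.rate_idx, 2]
        z = (pool.rates - mu) / sig
        alpha = mu / sig
        log_Phi = log_ndtr(alpha)
        ratio = np.exp(-0.5 * alpha**2 - _SQ2PI - log_Phi)
        ll += float(np.sum(-np.log(sig) - 0.5 * z**2 - _SQ2PI - log_Phi))
        g[:, 1] += seg(pool.rate_idx, z / sig - ratio / sig)
        g[:, 2] += seg(pool.rate_idx, (z**2 - 1.0) / sig + alpha * ratio / sig)

    # routing
    if len(pool.rx):
        T1 = theta[pool.r_idx, 4]
        T2 = theta[pool.r_idx, 5]
        eta = T1 * (pool.rx - T2)
        sgn = np.where(pool.r_to_L, 1.0, -1.0)
        ll += float(np.sum(-np.logaddexp(0.0, -sgn * eta)))
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-eta))
        deta = np.where(pool.r_to_L, 1.0 - p, -p)
        g[:, 4] += seg(pool.r_idx, deta * (pool.rx - T2))
        g[:, 5] += seg(pool.r_idx, -deta * T1)

    # short pauses
    if len(pool.s_d):
        lS = theta[pool.s_idx, 3]
        obs = ~pool.s_cens
        ll += float(np.sum(np.log(lS[obs])) - np.sum(lS * pool.s_d))
        g[:, 3] += seg(pool.s_idx[obs], 1.0 / lS[obs]) - seg(pool.s_idx, pool.s_d)

    # intermeal intervals
    if len(pool.l_d):
        L1 = theta[pool.l_idx, 6]
        L2 = theta[pool.l_idx, 7]
        lam, dA, dB = sqrt_hazard_terms_arr(pool.l_x0, pool.l_d, L1, L2, gut.k)
        ll += float(-np.sum(lam))
        gA = -dA
        gB = -dB
        obs = ~pool.l_cens
        if np.any(obs):
            x_t = empty_fullness_vec(pool.l_x0[obs], pool.l_d[obs], gut)
            denom = L1[obs] + L2[obs] * x_t
            ll += float(-np.sum(np.log(denom)))
            gA[obs] -= 1.0 / denom
            gB[obs] -= x_t / denom
        g[:, 6] += seg(pool.l_idx, gA)
        g[:, 7] += seg(pool.l_idx, gB)

    return ll, g
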