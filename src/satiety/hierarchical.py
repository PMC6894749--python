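"""Bayesian hierarchical model of a group of individuals.

Each individual j has an eight-parameter behavioural vector theta_j,
modelled on a transformed scale (log10 for the positive parameters, raw for
T1 and T2) as

    theta~_j ~ Normal(mu, Sigma),       Sigma = diag(tau) Omega diag(tau),
    tau_i    ~ HalfCauchy(tau_scale),   Omega ~ LKJ(eta),
    mu       ~ Normal(mu_star, mu_prior_sd).

Sampling uses the package's own NUTS kernel with fully analytic gradients.
The correlation matrix is parametrised through the canonical partial
correlations of its Cholesky factor (tanh-transformed to the real line); in
that parametrisation the LKJ prior, its transform Jacobian and their
gradients collapse to independent per-coordinate terms, which keeps the
posterior geometry simple and the gradient exact.

The default parametrisation is non-centred (theta~_j = mu + diag(tau) L z_j
with z_j standard normal), which removes the funnel geometry typical of
hierarchical models; a centred variant is provided for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular

from .gut import GutModel
from .likelihood import SequenceStats, sequence_loglik_and_grad
from .nuts import nuts_sample
from .params import LN10, LOG10_MASK, N_PARAMS, ModelParams, back_transform
from .simulate import FeedingSequence, simulate

__all__ = [
    "HyperPriorConfig",
    "GroupPosterior",
    "sample_group_prior",
    "fit_hierarchical",
    "posterior_predictive_intake",
]

_D = N_PARAMS
_M = _D * (_D - 1) // 2  # free correlation coordinates


@dataclass(frozen=True)
class HyperPriorConfig:
    """Hyperpriors of the group model (transformed scale)."""

    mu_star: tuple = (-3.0, -3.0, -3.0, 1.0, 1.0, -1.0, 3.0, 3.0)
    mu_prior_sd: float = 2.0
    tau_scale: float = 2.5
    lkj_eta: float = 2.0

    def __post_init__(self) -> None:
        if len(self.mu_star) != _D:
            raise ValueError(f"mu_star must have length {_D}")
        if self.tau_scale <= 0 or self.lkj_eta <= 0 or self.mu_prior_sd <= 0:
            raise ValueError("tau_scale, lkj_eta and mu_prior_sd must be > 0")

    @property
    def mu_star_arr(self) -> np.ndarray:
        return np.asarray(self.mu_star, dtype=float)


# ---------------------------------------------------------------------------
# correlation Cholesky parametrisation
# ---------------------------------------------------------------------------

def _lkj_coef(eta: float) -> np.ndarray:
    """Per-coordinate exponent c for the y-space LKJ(eta) log-density.

    The prior density of the unconstrained coordinate y_{ij} (row i, column
    j, 0-based, j < i) is proportional to (1 - tanh(y)^2)^c with
    c = eta + (d - j - 2) / 2 — the combination of the LKJ-Cholesky density
    and the full transform Jacobian; it depends only on the column.
    """
    c = np.empty(_M)
    idx = 0
    for i in range(1, _D):
        for j in range(i):
            c[idx] = eta + (_D - j - 2) / 2.0
            idx += 1
    return c


def corr_chol_from_y(y: np.ndarray) -> np.ndarray:
    """Lower-Cholesky factor of a correlation matrix from unconstrained y."""
    z = np.tanh(y)
    L = np.zeros((_D, _D))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, _D):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[idx] * math.sqrt(rem)
            rem *= 1.0 - z[idx] ** 2
            idx += 1
        L[i, i] = math.sqrt(rem)
    return L


def _corr_chol_vjp(y: np.ndarray, L: np.ndarray, gL: np.ndarray) -> np.ndarray:
    """Map a gradient w.r.t. L (lower incl. diagonal) to a gradient w.r.t. y."""
    z = np.tanh(y)
    gy = np.zeros(_M)
    idx0 = 0
    for i in range(1, _D):
        rem = 1.0
        for j in range(i):
            k = idx0 + j
            croot = math.sqrt(rem)
            tail = 0.0
            for m in range(j + 1, i + 1):
                tail += gL[i, m] * L[i, m]
            one_minus = 1.0 - z[k] ** 2
            dz = gL[i, j] * croot - z[k] / one_minus * tail
            gy[k] = dz * one_minus
            rem *= one_minus
        idx0 += i
    return gy


# ---------------------------------------------------------------------------
# prior sampling
# ---------------------------------------------------------------------------

@dataclass
class GroupDraw:
    mu: np.ndarray
    tau: np.ndarray
    corr_chol: np.ndarray
    theta_tilde: np.ndarray  # (n_individuals, 8), transformed scale

    @property
    def omega(self) -> np.ndarray:
        return self.corr_chol @ self.corr_chol.T

    @property
    def sigma(self) -> np.ndarray:
        return np.diag(self.tau) @ self.omega @ np.diag(self.tau)


def sample_group_prior(hyper: HyperPriorConfig, n_individuals: int,
                       rng: np.random.Generator,
                       mu: Optional[np.ndarray] = None,
                       tau: Optional[np.ndarray] = None,
                       corr_chol: Optional[np.ndarray] = None,
                       materialise: bool = True):
    """Ancestral draw mu -> Sigma -> individuals.

    Returns ``(GroupDraw, list[ModelParams])``.  Any of mu/tau/corr_chol can
    be pinned (useful for prior-predictive checks at fixed hyper-draws).
    With ``materialise=False`` the ModelParams list is skipped — under the
    heavy-tailed default hyperprior an occasional draw overflows the
    natural scale, which is fine for prior summaries but not for a
    validated parameter object.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if mu is None:
        mu = rng.normal(hyper.mu_star_arr, hyper.mu_prior_sd)
    if tau is None:
        tau = np.abs(hyper.tau_scale * rng.standard_cauchy(_D))
    if corr_chol is None:
        c = _lkj_coef(hyper.lkj_eta)
        z = 2.0 * rng.beta(c, c) - 1.0
        corr_chol = corr_chol_from_y(np.arctanh(np.clip(z, -1 + 1e-12, 1 - 1e-12)))
    z_ind = rng.normal(size=(n_individuals, _D))
    theta_tilde = mu + (tau * (z_ind @ corr_chol.T))
    draw = GroupDraw(mu=np.asarray(mu, float), tau=np.asarray(tau, float),
                     corr_chol=corr_chol, theta_tilde=theta_tilde)
    if not materialise:
        return draw, None
    individuals = [ModelParams.from_transformed(t) for t in theta_tilde]
    return draw, individuals


# ---------------------------------------------------------------------------
# posterior
# ---------------------------------------------------------------------------

def _chain_to_tilde(g_nat: np.ndarray, theta_nat: np.ndarray) -> np.ndarray:
    g = g_nat.copy()
    g[LOG10_MASK] = g_nat[LOG10_MASK] * theta_nat[LOG10_MASK] * LN10
    return g


class _HierarchicalTarget:
    """Log-posterior and gradient in the unconstrained vector w."""

    def __init__(self, stats_per_ind, gut: GutModel, hyper: HyperPriorConfig,
                 n_individuals: int, centred: bool = False,
                 use_likelihood: bool = True):
        self.stats = stats_per_ind
        self.gut = gut
        self.hyper = hyper
        self.J = n_individuals
        self.centred = centred
        self.use_likelihood = use_likelihood
        self.lkj_c = _lkj_coef(hyper.lkj_eta)
        self.dim = 2 * _D + _M + self.J * _D
        self._pool = None
        if use_likelihood and gut.law == "sqrt" and self.J > 0:
            from .likelihood import PooledStats
            self._pool = PooledStats.from_stats(stats_per_ind)

    # layout: [mu (D) | log tau (D) | y (M) | per-individual block (J*D)]
    def unpack(self, w):
        mu = w[:_D]
        v = w[_D:2 * _D]
        y = w[2 * _D:2 * _D + _M]
        block = w[2 * _D + _M:].reshape(self.J, _D)
        return mu, v, y, block

    def pack(self, mu, v, y, block):
        return np.concatenate([mu, v, y, np.asarray(block).ravel()])

    def _loglik_terms(self, theta_tilde):
        """Sum of per-individual log-likelihoods and gradients (tilde scale)."""
        if self._pool is not None:
            from .likelihood import pooled_loglik_and_grad
            with np.errstate(all="ignore"):
                theta_nat = back_transform(theta_tilde)
                if not np.all(np.isfinite(theta_nat)):
                    return -np.inf, np.zeros((self.J, _D))
                ll, g_nat = pooled_loglik_and_grad(self._pool, theta_nat, self.gut)
                g = g_nat
                g[:, LOG10_MASK] = g_nat[:, LOG10_MASK] * theta_nat[:, LOG10_MASK] * LN10
            return ll, g
        ll = 0.0
        g = np.zeros((self.J, _D))
        for j in range(self.J):
            theta_nat = back_transform(theta_tilde[j])
            for st in self.stats[j]:
                lli, gi = sequence_loglik_and_grad(st, theta_nat, self.gut)
                ll += lli
                g[j] += _chain_to_tilde(gi, theta_nat)
        return ll, g

    def __call__(self, w):
        # far-out leapfrog states can overflow; the sampler treats the
        # resulting non-finite energies as divergences
        with np.errstate(all="ignore"):
            return self._logp_and_grad(w)

    def _logp_and_grad(self, w):
        mu, v, y, block = self.unpack(w)
        tau = np.exp(v)
        L = corr_chol_from_y(y)
        h = self.hyper

        logp = 0.0
        gmu = np.zeros(_D)
        gv = np.zeros(_D)
        gL = np.zeros((_D, _D))

        # hyperpriors
        sd = h.mu_prior_sd
        logp += float(np.sum(-0.5 * ((mu - h.mu_star_arr) / sd) ** 2))
        gmu += -(mu - h.mu_star_arr) / sd**2
        s = h.tau_scale
        ratio2 = (tau / s) ** 2
        logp += float(np.sum(v - np.log1p(ratio2)))  # HalfCauchy + log|J|
        gv += 1.0 - 2.0 * ratio2 / (1.0 + ratio2)
        th_y = np.tanh(y)
        logp += float(np.sum(self.lkj_c * np.log1p(-th_y**2)))
        gy = -2.0 * self.lkj_c * th_y

        if self.centred:
            theta_tilde = block
            r = (theta_tilde - mu) / tau  # (J, D)
            q = solve_triangular(L, r.T, lower=True).T  # (J, D)
            logp += float(-0.5 * np.sum(q**2)) - self.J * float(np.sum(v))
            logp += -self.J * float(np.sum(np.log(np.diag(L))))
            Ltq = solve_triangular(L.T, q.T, lower=False).T  # (J, D) = L^{-T} q
            gtheta = -Ltq / tau
            gmu += np.sum(Ltq / tau, axis=0)
            gv += np.sum(Ltq * r, axis=0) - self.J
            gL += sum(np.outer(Ltq[j], q[j]) for j in range(self.J))
            gL -= self.J * np.diag(1.0 / np.diag(L))
            if self.use_likelihood:
                ll, gtil = self._loglik_terms(theta_tilde)
                logp += ll
                gtheta = gtheta + gtil
            gblock = gtheta
        else:
            z = block
            u = z @ L.T  # (J, D)
            theta_tilde = mu + tau * u
            logp += float(-0.5 * np.sum(z**2))
            gz = -z
            if self.use_likelihood:
                ll, gtil = self._loglik_terms(theta_tilde)
                logp += ll
                gmu += np.sum(gtil, axis=0)
                gv += np.sum(gtil * u, axis=0) * tau
                gz = gz + (tau * gtil) @ L
                gL += (tau * gtil).T @ z
            gblock = gz

        gy += _corr_chol_vjp(y, L, np.tril(gL))
        grad = self.pack(gmu, gv, gy, gblock)
        return logp, grad


@dataclass
class GroupPosterior:
    """Posterior draws (chains x draws) with transform metadata."""

    mu: np.ndarray            # (C, N, D) transformed scale
    tau: np.ndarray           # (C, N, D)
    corr_chol: np.ndarray     # (C, N, D, D)
    theta_tilde: np.ndarray   # (C, N, J, D)
    hyper: HyperPriorConfig
    gut: GutModel
    subjects: list
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.theta_tilde.shape[2]

    def omega(self) -> np.ndarray:
        return np.einsum("cnij,cnkj->cnik", self.corr_chol, self.corr_chol)

    def to_inferencedata(self):
        import arviz as az

        return az.from_dict(posterior={
            "mu": self.mu, "tau": self.tau,
            "theta_tilde": self.theta_tilde,
        })

    def individual_params(self, j: int, reduce: str = "mean") -> ModelParams:
        """Plug-in ModelParams for individual j (posterior-mean by default)."""
        draws = self.theta_tilde[:, :, j, :].reshape(-1, _D)
        if reduce == "mean":
            return ModelParams.from_transformed(draws.mean(axis=0))
        if reduce == "median":
            return ModelParams.from_transformed(np.median(draws, axis=0))
        raise ValueError("reduce must be 'mean' or 'median'")

    def group_mean_params(self) -> ModelParams:
        """Back-transformed group posterior-mean parameter vector."""
        return ModelParams.from_transformed(self.mu.reshape(-1, _D).mean(axis=0))

    def draw_individual(self, j: int, chain: int, draw: int) -> ModelParams:
        return ModelParams.from_transformed(self.theta_tilde[chain, draw, j])

    def mu_interval(self, prob: float = 0.9) -> np.ndarray:
        """(2, D) central credible interval for each component of mu."""
        flat = self.mu.reshape(-1, _D)
        a = (1.0 - prob) / 2.0
        return np.quantile(flat, [a, 1.0 - a], axis=0)

    def summary(self):
        import pandas as pd

        from .params import PARAM_NAMES

        flat = self.mu.reshape(-1, _D)
        lo, hi = self.mu_interval(0.9)
        return pd.DataFrame({
            "param": PARAM_NAMES,
            "mu_mean": flat.mean(axis=0),
            "mu_sd": flat.std(axis=0),
            "mu_hdi5": lo, "mu_hdi95": hi,
            "tau_mean": self.tau.reshape(-1, _D).mean(axis=0),
        })


def _normalise_dataset(dataset) -> list:
    out = []
    for item in dataset:
        if isinstance(item, (FeedingSequence, SequenceStats)):
            out.append([item])
        else:
            seqs = list(item)
            if not seqs:
                raise ValueError("individual with no sequences")
            out.append(seqs)
    return out


def fit_hierarchical(dataset, gut: GutModel,
                     hyper: Optional[HyperPriorConfig] = None,
                     tune: int = 500, draws: int = 500, chains: int = 2,
                     rng: Optional[np.random.Generator] = None,
                     seed: Optional[int] = None,
                     target_accept: float = 0.9,
                     max_treedepth: int = 10,
                     centred: bool = False,
                     use_likelihood: bool = True,
                     n_individuals: Optional[int] = None,
                     init: str = "moment",
                     max_divergence_frac: float = 0.25) -> GroupPosterior:
    """Fit the hierarchical model by NUTS.

    ``dataset`` is a list over individuals; each element is a
    FeedingSequence or a list of them.  For prior-only runs
    (``use_likelihood=False``) dataset may be None with ``n_individuals``
    given.  Raises if the divergent-transition fraction exceeds
    ``max_divergence_frac``.
    """
    hyper = hyper or HyperPriorConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    if use_likelihood:
        if not dataset:
            raise ValueError("empty dataset")
        groups = _normalise_dataset(dataset)
        if len(groups) < 1:
            raise ValueError("need at least one individual")
        stats = []
        subjects = []
        for seqs in groups:
            st = []
            for s in seqs:
                seq_stats = (s if isinstance(s, SequenceStats)
                             else SequenceStats.from_sequence(s, gut))
                st.append(seq_stats)
            stats.append(st)
            subjects.append(getattr(seqs[0], "subject", f"ind{len(subjects)}"))
        J = len(stats)
        if any(sum(x.n_meals for x in st) < 1 for st in stats):
            raise ValueError("every individual needs at least one complete meal")
    else:
        if n_individuals is None:
            n_individuals = 0
        J = n_individuals
        stats = [[] for _ in range(J)]
        subjects = [f"prior{j}" for j in range(J)]

    target = _HierarchicalTarget(stats, gut, hyper, J, centred=centred,
                                 use_likelihood=use_likelihood)

    # initial point: crude moment-matching start (never a MAP fit) or the
    # hyperprior mean, plus per-chain jitter
    if init == "moment" and use_likelihood:
        from .likelihood import _moment_init
        flat = [s for st in stats for s in st]
        mu0 = _moment_init(flat).to_transformed()
    else:
        mu0 = hyper.mu_star_arr.copy()
    v0 = np.full(_D, np.log(0.2))
    y0 = np.zeros(_M)

    mu_chains, tau_chains, L_chains, tt_chains = [], [], [], []
    div_total = 0
    accept_stats = []
    for c in range(chains):
        crng = np.random.default_rng(rng.integers(2**31 - 1))
        block0 = (np.tile(mu0, (J, 1)) + 0.05 * crng.normal(size=(J, _D))
                  if centred else 0.1 * crng.normal(size=(J, _D)))
        w0 = target.pack(mu0 + 0.1 * crng.normal(size=_D),
                         v0 + 0.1 * crng.normal(size=_D),
                         y0 + 0.01 * crng.normal(size=_M), block0)
        lp0, _ = target(w0)
        if not np.isfinite(lp0):
            raise RuntimeError("non-finite log-posterior at the initial point")
        res = nuts_sample(target, w0, tune, draws, crng,
                          max_treedepth=max_treedepth,
                          target_accept=target_accept)
        div_total += res.divergences
        accept_stats.append(res.accept_stat)
        mus = np.empty((draws, _D))
        taus = np.empty((draws, _D))
        Ls = np.empty((draws, _D, _D))
        tts = np.empty((draws, J, _D))
        for n in range(draws):
            mu, v, y, block = target.unpack(res.draws[n])
            mus[n] = mu
            taus[n] = np.exp(v)
            L = corr_chol_from_y(y)
            Ls[n] = L
            if centred:
                tts[n] = block
            else:
                tts[n] = mu + taus[n] * (block @ L.T)
        mu_chains.append(mus)
        tau_chains.append(taus)
        L_chains.append(Ls)
        tt_chains.append(tts)

    post = GroupPosterior(
        mu=np.stack(mu_chains), tau=np.stack(tau_chains),
        corr_chol=np.stack(L_chains), theta_tilde=np.stack(tt_chains),
        hyper=hyper, gut=gut, subjects=subjects)

    import arviz as az

    idata = post.to_inferencedata()
    ess = az.ess(idata)
    rhat_mu = (float(np.max(az.rhat(idata)["mu"].values)) if chains > 1
               else float("nan"))
    post.diagnostics = {
        "divergences": int(div_total),
        "divergence_frac": div_total / max(chains * draws, 1),
        "accept_stat": float(np.mean(accept_stats)),
        "rhat_mu_max": rhat_mu,
        "ess_mu_min": float(np.min(ess["mu"].values)),
    }
    if post.diagnostics["divergence_frac"] > max_divergence_frac:
        raise RuntimeError(
            f"{div_total} divergent transitions "
            f"({100 * post.diagnostics['divergence_frac']:.1f}% > "
            f"{100 * max_divergence_frac:.0f}% allowed); "
            "consider raising target_accept or reparametrising")
    return post


def posterior_predictive_intake(posterior: GroupPosterior, individual,
                                window: tuple, x_init: float, n_draws: int,
                                rng: np.random.Generator,
                                record_next_meal: bool = False) -> dict:
    """Posterior-predictive food intake for one individual.

    Each of ``n_draws`` predictive replicates draws a parameter vector from
    the individual's posterior, simulates the window, and records total
    intake (and optionally the first meal-start time).  Returns samples,
    mean and a central 90% interval.
    """
    if isinstance(individual, str):
        j = posterior.subjects.index(individual)
    else:
        j = int(individual)
    C, N = posterior.n_chains, posterior.n_draws
    intakes = np.empty(n_draws)
    next_meal = np.full(n_draws, np.nan)
    for i in range(n_draws):
        c = rng.integers(C)
        n = rng.integers(N)
        params = posterior.draw_individual(j, c, n)
        seq, _ = simulate(params, posterior.gut, window, x_init=x_init, rng=rng)
        intakes[i] = sum(b.amount for b in seq.bouts())
        if record_next_meal:
            bouts = seq.bouts()
            if bouts:
                next_meal[i] = bouts[0].start - window[0]
    out = {
        "intake_samples": intakes,
        "mean": float(intakes.mean()),
        "interval90": (float(np.quantile(intakes, 0.05)),
                       float(np.quantile(intakes, 0.95))),
    }
    if record_next_meal:
        out["next_meal_samples"] = next_meal
    return out
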