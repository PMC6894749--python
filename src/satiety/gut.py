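"""Deterministic gut (fullness) dynamics.

Fullness ``x`` (grams of contents in the stomach + small intestine) rises
linearly while the animal feeds and decays while it does not.  The default
emptying law is the square-root law

    dx/dt = -k * sqrt(x),

whose solution ``x(t) = (sqrt(x0) - k t / 2)**2`` reaches zero in finite time
``t_empty = 2 sqrt(x0) / k``.  A linear law (``dx/dt = -k x``) and a general
power law (``dx/dt = -k x**gamma``, ``0 < gamma < 1``) are provided so that
downstream analyses can be checked for robustness to the emptying model.

The module also provides the integrated intermeal-interval hazard

    Lambda(t) = int_0^t dtau / (L1 + L2 * x(tau)),

which is piecewise closed-form under the square-root law (an arctan term
while the gut is emptying, then ``(t - t_empty)/L1``), together with its
partial derivatives in ``L1`` and ``L2`` — the quantities the event
likelihood and its gradient are built from.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "GutModel",
    "FullnessTrajectory",
    "empty_fullness",
    "time_to_empty",
    "empty_fullness_vec",
    "integrated_imi_hazard",
    "imi_hazard_terms",
    "sqrt_hazard_terms_arr",
    "invert_imi_hazard",
    "fullness_trajectory",
]

_LAWS = ("sqrt", "linear", "power")


@dataclass(frozen=True)
class GutModel:
    """Emptying law + rate constant defining the deterministic fullness flow.

    Parameters
    ----------
    law:
        ``"sqrt"`` (default), ``"linear"`` or ``"power"``.
    k:
        Emptying rate constant, units g**(1-gamma)/s (gamma = 1/2 for the
        square-root law).  The default 0.00055 empties a 4 g load in about
        two hours.
    gamma:
        Exponent for the ``"power"`` law; fixed at 0.5 / 1.0 for the sqrt /
        linear laws.
    epsilon_empty:
        Numerical floor (g) below which fullness is treated as exactly zero;
        for the linear law this is also what makes "time to empty" finite.
    """

    law: str = "sqrt"
    k: float = 0.00055
    gamma: float = 0.5
    epsilon_empty: float = 1e-9

    def __post_init__(self) -> None:
        if self.law not in _LAWS:
            raise ValueError(f"unknown emptying law {self.law!r}; use one of {_LAWS}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError("k must be finite and > 0")
        if self.epsilon_empty < 0:
            raise ValueError("epsilon_empty must be >= 0")
        if self.law == "power" and not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")

    @property
    def exponent(self) -> float:
        """Effective emptying exponent gamma."""
        if self.law == "sqrt":
            return 0.5
        if self.law == "linear":
            return 1.0
        return self.gamma

    def with_k_factor(self, factor: float) -> "GutModel":
        """Same law with ``k`` scaled by ``factor`` (motility modulation)."""
        if factor <= 0:
            raise ValueError("k factor must be > 0")
        return GutModel(self.law, self.k * factor, self.gamma, self.epsilon_empty)


def empty_fullness(x0: float, dt, gut: GutModel):
    """Fullness after emptying for ``dt`` seconds from ``x0`` grams.

    Accepts scalar or array ``dt``; vectorised over ``dt``.
    """
    dt = np.asarray(dt, dtype=float)
    if x0 < 0:
        raise ValueError("x0 must be >= 0")
    if np.any(dt < 0):
        raise ValueError("dt must be >= 0")
    if x0 <= gut.epsilon_empty:
        return np.zeros_like(dt) if dt.ndim else 0.0
    g = gut.exponent
    if g < 1.0:
        p = 1.0 - g
        root = np.maximum(x0**p - p * gut.k * dt, 0.0)
        x = root ** (1.0 / p)
    else:
        x = x0 * np.exp(-gut.k * dt)
    x = np.where(x <= gut.epsilon_empty, 0.0, x)
    return x if dt.ndim else float(x)


def empty_fullness_vec(x0, dt, gut: GutModel) -> np.ndarray:
    """Vectorised :func:`empty_fullness` over paired arrays x0, dt."""
    x0 = np.asarray(x0, dtype=float)
    dt = np.asarray(dt, dtype=float)
    g = gut.exponent
    if g < 1.0:
        p = 1.0 - g
        root = np.maximum(x0**p - p * gut.k * dt, 0.0)
        x = root ** (1.0 / p)
    else:
        x = x0 * np.exp(-gut.k * dt)
    return np.where((x <= gut.epsilon_empty) | (x0 <= gut.epsilon_empty), 0.0, x)


def time_to_empty(x0: float, gut: GutModel) -> float:
    """Smallest t with ``empty_fullness(x0, t) == 0`` (may be +inf).

    For the square-root law this is ``2 sqrt(x0) / k``.  The linear law never
    reaches exact zero; the time to decay to ``epsilon_empty`` is returned
    (+inf when ``epsilon_empty == 0``).
    """
    if x0 < 0:
        raise ValueError("x0 must be >= 0")
    if x0 <= gut.epsilon_empty:
        return 0.0
    g = gut.exponent
    if g < 1.0:
        p = 1.0 - g
        return x0**p / (p * gut.k)
    if gut.epsilon_empty == 0.0:
        return np.inf
    return np.log(x0 / gut.epsilon_empty) / gut.k


def _sqrt_hazard_terms(x0, t, L1: float, L2: float, k: float):
    """Lambda(t) and d(Lambda)/dL1, d(Lambda)/dL2 for the sqrt law.

    Vectorised over ``x0`` and ``t`` (broadcast together).  Uses the
    substitution u = sqrt(x) so that every integral reduces to a rational /
    arctan antiderivative; a series branch keeps the L2 -> 0 limit stable.
    """
    x0 = np.asarray(x0, dtype=float)
    t = np.asarray(t, dtype=float)
    u0 = np.sqrt(x0)
    t_e = 2.0 * u0 / k
    # sqrt-of-fullness at min(t, t_empty); tail time spent fully empty
    ue = np.maximum(u0 - k * t / 2.0, 0.0)
    tail = np.maximum(t - t_e, 0.0)

    a, b = L1, L2
    if b == 0.0:
        lam = t / a
        dA = -t / a**2
        dB = -(2.0 / (3.0 * k)) * (u0**3 - ue**3) / a**2
        return lam, dA, dB

    # stable branch for very small L2 * x0 relative to L1
    small = b * np.maximum(x0, 0.0) < 1e-10 * a
    s = np.sqrt(a * b)
    r = np.sqrt(b / a)
    at0 = np.arctan(u0 * r)
    ate = np.arctan(ue * r)
    lam = (2.0 / (k * s)) * (at0 - ate) + tail / a

    def I1(u, atu):
        return u / (2.0 * a * (a + b * u**2)) + atu / (2.0 * a * s)

    def I2(u, atu):
        return (atu / (2.0 * s) - u / (2.0 * (a + b * u**2))) / b

    dA = -(2.0 / k) * (I1(u0, at0) - I1(ue, ate)) - tail / a**2
    dB = -(2.0 / k) * (I2(u0, at0) - I2(ue, ate))

    if np.any(small):
        lam_s = 2.0 * (u0 - ue) / (k * a) + tail / a
        dA_s = -2.0 * (u0 - ue) / (k * a**2) - tail / a**2
        dB_s = -(2.0 / (3.0 * k)) * (u0**3 - ue**3) / a**2
        lam = np.where(small, lam_s, lam)
        dA = np.where(small, dA_s, dA)
        dB = np.where(small, dB_s, dB)
    return lam, dA, dB


def sqrt_hazard_terms_arr(x0, t, L1, L2, k: float):
    """Array version of the sqrt-law hazard terms with per-element L1, L2.

    All of x0, t, L1, L2 broadcast together; returns (Lambda, dL1, dL2).
    Used by the pooled multi-individual likelihood, where each event can
    belong to a different parameter vector.
    """
    x0, t, a, b = np.broadcast_arrays(*map(np.asarray, (x0, t, L1, L2)))
    x0 = x0.astype(float)
    t = t.astype(float)
    a = a.astype(float)
    b = b.astype(float)
    u0 = np.sqrt(x0)
    t_e = 2.0 * u0 / k
    ue = np.maximum(u0 - k * t / 2.0, 0.0)
    tail = np.maximum(t - t_e, 0.0)

    small = b * x0 < 1e-10 * a  # includes b == 0
    bs = np.where(small, 1.0, b)  # safe divisor for the arctan branch
    s = np.sqrt(a * bs)
    r = np.sqrt(bs / a)
    at0 = np.arctan(u0 * r)
    ate = np.arctan(ue * r)
    denom0 = a + bs * u0**2
    denome = a + bs * ue**2
    lam = (2.0 / (k * s)) * (at0 - ate) + tail / a
    i1 = (u0 / (2.0 * a * denom0) + at0 / (2.0 * a * s)
          - ue / (2.0 * a * denome) - ate / (2.0 * a * s))
    i2 = ((at0 / (2.0 * s) - u0 / (2.0 * denom0))
          - (ate / (2.0 * s) - ue / (2.0 * denome))) / bs
    dA = -(2.0 / k) * i1 - tail / a**2
    dB = -(2.0 / k) * i2

    lam_s = 2.0 * (u0 - ue) / (k * a) + tail / a
    dA_s = -2.0 * (u0 - ue) / (k * a**2) - tail / a**2
    dB_s = -(2.0 / (3.0 * k)) * (u0**3 - ue**3) / a**2
    return (np.where(small, lam_s, lam),
            np.where(small, dA_s, dA),
            np.where(small, dB_s, dB))


def _linear_hazard(x0: float, t, L1: float, L2: float, k: float):
    """Closed-form Lambda(t) for the linear law (exponential decay)."""
    t = np.asarray(t, dtype=float)
    if L2 == 0.0 or x0 <= 0.0:
        return t / L1
    # int_0^t dtau / (L1 + L2 x0 e^{-k tau})
    #   = (1/(L1 k)) [log(L1 e^{k tau} + L2 x0)]_0^t
    return (np.log(L1 * np.exp(k * t) + L2 * x0) - np.log(L1 + L2 * x0)) / (L1 * k)


def imi_hazard_terms(x0, t, L1: float, L2: float, gut: GutModel):
    """(Lambda, dLambda/dL1, dLambda/dL2) along the emptying trajectory.

    Closed form for the sqrt law; numerical quadrature otherwise (gradient
    integrands are still exact integrals, evaluated numerically).
    """
    if gut.law == "sqrt":
        return _sqrt_hazard_terms(x0, t, L1, L2, gut.k)

    x0_arr = np.atleast_1d(np.asarray(x0, dtype=float))
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    x0_b, t_b = np.broadcast_arrays(x0_arr, t_arr)
    lam = np.empty(x0_b.shape)
    dA = np.empty(x0_b.shape)
    dB = np.empty(x0_b.shape)
    for idx in np.ndindex(x0_b.shape):
        xi, ti = float(x0_b[idx]), float(t_b[idx])
        if gut.law == "linear" and gut.epsilon_empty <= 1e-12:
            lam[idx] = _linear_hazard(xi, ti, L1, L2, gut.k)
        else:
            lam[idx] = quad(
                lambda tau: 1.0 / (L1 + L2 * empty_fullness(xi, tau, gut)),
                0.0, ti, limit=200)[0]
        dA[idx] = -quad(
            lambda tau: 1.0 / (L1 + L2 * empty_fullness(xi, tau, gut)) ** 2,
            0.0, ti, limit=200)[0]
        dB[idx] = -quad(
            lambda tau: empty_fullness(xi, tau, gut)
            / (L1 + L2 * empty_fullness(xi, tau, gut)) ** 2,
            0.0, ti, limit=200)[0]
    if np.ndim(x0) == 0 and np.ndim(t) == 0:
        return float(lam[0]), float(dA[0]), float(dB[0])
    return lam, dA, dB


def integrated_imi_hazard(x0, t, L1: float, L2: float, gut: GutModel):
    """Integrated meal-initiation hazard Lambda(t) = int_0^t dtau/(L1+L2 x(tau)).

    Continuous, nondecreasing, Lambda(0) = 0.  Raises on non-positive L1 or
    negative L2/x0/t.
    """
    if not (np.isfinite(L1) and L1 > 0):
        raise ValueError("L1 must be finite and > 0")
    if L2 < 0:
        raise ValueError("L2 must be >= 0")
    if np.any(np.asarray(x0) < 0) or np.any(np.asarray(t) < 0):
        raise ValueError("x0 and t must be >= 0")
    lam, _, _ = imi_hazard_terms(x0, t, L1, L2, gut)
    return lam


def invert_imi_hazard(x0: float, target: float, L1: float, L2: float,
                      gut: GutModel, tol: float = 1e-6) -> float:
    """Unique t with ``integrated_imi_hazard(x0, t) == target``.

    Exact piecewise inversion for the sqrt law; bracketed root-finding
    (absolute tolerance ``tol`` seconds) for other laws.
    """
    if target < 0:
        raise ValueError("target must be >= 0")
    if target == 0.0:
        return 0.0
    if gut.law == "sqrt":
        k = gut.k
        if L2 == 0.0 or x0 <= gut.epsilon_empty:
            return target * L1
        u0 = np.sqrt(x0)
        t_e = 2.0 * u0 / k
        s = np.sqrt(L1 * L2)
        r = np.sqrt(L2 / L1)
        lam_e = (2.0 / (k * s)) * np.arctan(u0 * r)
        if target >= lam_e:
            return float(t_e + (target - lam_e) * L1)
        a_t = np.arctan(u0 * r) - target * k * s / 2.0
        ue = np.tan(a_t) / r
        return float(2.0 * (u0 - ue) / k)

    from scipy.optimize import brentq

    t_e = time_to_empty(x0, gut)
    if not np.isfinite(t_e):
        t_e = np.log(max(x0 / max(gut.epsilon_empty, 1e-12), 2.0)) / gut.k
    hi = L1 * target + t_e
    while integrated_imi_hazard(x0, hi, L1, L2, gut) < target:
        hi *= 2.0
    return float(brentq(
        lambda t: integrated_imi_hazard(x0, t, L1, L2, gut) - target,
        0.0, hi, xtol=tol))


@dataclass
class FullnessTrajectory:
    """Piecewise-analytic fullness record x(t) over an observation window.

    ``segments`` is an ordered list of tuples
    ``(start, end, kind, x_start, rate)`` where ``kind`` is ``"filling"``
    (linear rise at ``rate`` g/s) or ``"emptying"`` (the gut law; ``rate``
    holds the gut's k for reference).
    """

    segments: list
    gut: GutModel

    def __post_init__(self) -> None:
        self._starts = [s[0] for s in self.segments]

    @property
    def window(self) -> tuple[float, float]:
        return self.segments[0][0], self.segments[-1][1]

    def fullness(self, t):
        """Evaluate x(t); vectorised; clamps to the covered window."""
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.window
        out = np.empty_like(t)
        for i, ti in enumerate(t):
            ti = min(max(ti, lo), hi)
            j = bisect.bisect_right(self._starts, ti) - 1
            j = max(j, 0)
            start, end, kind, x_start, rate = self.segments[j]
            dt = ti - start
            if kind == "filling":
                out[i] = x_start + rate * dt
            else:
                out[i] = empty_fullness(x_start, dt, self.gut)
        return float(out[0]) if scalar else out

    def sample(self, n: int = 500) -> np.ndarray:
        """(n, 2) array of (time_s, fullness_g) on a uniform grid."""
        lo, hi = self.window
        ts = np.linspace(lo, hi, n)
        return np.column_stack([ts, self.fullness(ts)])

    def to_text(self, path, n: int = 500, delimiter: str = "\t") -> None:
        """Export the trajectory as two-column delimited text."""
        np.savetxt(path, self.sample(n), delimiter=delimiter,
                   header=f"time_s{delimiter}fullness_g", comments="")


def fullness_trajectory(seq, gut: GutModel, x_init: float = 0.0) -> FullnessTrajectory:
    """Fullness implied by an observed event sequence.

    Filling proceeds at each bout's realised rate (amount/duration); all
    other time (explicit pauses and implicit gaps) empties under the gut
    law.  Digestion during feeding is neglected, so fullness at bout end
    equals fullness at bout start plus the amount consumed.  Sham bouts
    (``amount`` recorded but ``fills_gut=False``) leave fullness unchanged.
    """
    if x_init < 0:
        raise ValueError("x_init must be >= 0")
    win_start, win_end = seq.window
    segments = []
    t = win_start
    x = float(x_init)
    last_end = win_start
    for ev in seq.events:
        if ev.start < last_end - 1e-9:
            raise ValueError(
                f"overlapping events: event at t={ev.start} begins before "
                f"previous event ends at t={last_end}")
        if ev.start > t + 1e-12:  # implicit gap -> emptying
            segments.append((t, ev.start, "emptying", x, gut.k))
            x = empty_fullness(x, ev.start - t, gut)
            t = ev.start
        end = min(ev.start + ev.duration, win_end)
        if ev.kind == "bout":
            rate = ev.amount / ev.duration if ev.duration > 0 else 0.0
            fills = getattr(ev, "fills_gut", True)
            seg_rate = rate if fills else 0.0
            segments.append((t, end, "filling", x, seg_rate))
            x = x + seg_rate * (end - t)
        else:
            segments.append((t, end, "emptying", x, gut.k))
            x = empty_fullness(x, end - t, gut)
        t = end
        last_end = end
    if t < win_end or not segments:
        segments.append((t, win_end, "emptying", x, gut.k))
    return FullnessTrajectory(segments=segments, gut=gut)
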