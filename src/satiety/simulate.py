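"""Generative engine for the feeding process.

The behavioural state alternates between feeding bouts (F), short
within-meal pauses (S) and long intermeal intervals (L).  Bout and
short-pause durations are exponential; the per-bout feeding rate is
normal truncated at zero; at the end of each bout the meal terminates
(F -> L) with probability sigmoid(T1 * (x - T2)) evaluated at the
bout-end fullness, otherwise a short pause follows (F -> S).  The
intermeal interval is drawn exactly, by inverting the integrated
fullness-dependent hazard 1 / (L1 + L2 x(t)) along the emptying
trajectory.

The same engine doubles as the package's synthetic-data generator:
simulated sequences carry ground-truth pause classes and per-event
fullness, so every downstream estimator can be validated against known
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .gut import GutModel, empty_fullness, fullness_trajectory, invert_imi_hazard
from .params import ModelParams

__all__ = [
    "EventRecord",
    "FeedingSequence",
    "InterventionSpec",
    "termination_probability",
    "sample_bout",
    "sample_imi_duration",
    "simulate",
    "summarise",
    "SequenceSummary",
]


@dataclass
class EventRecord:
    """A single bout or pause.

    ``amount`` is grams consumed (zero for pauses); for bouts it equals the
    realised rate times the (possibly censored) duration.  ``pause_class``
    is ``"S"``, ``"L"`` or ``"unknown"`` for pauses, ``None`` for bouts.
    ``next_state`` records the simulator's routing decision after a bout
    ("S"/"L"), when known.  ``fills_gut`` is False for sham bouts.
    """

    kind: str  # "bout" | "pause"
    start: float
    duration: float
    amount: float = 0.0
    pause_class: Optional[str] = None
    fullness_at_start: Optional[float] = None
    censored: bool = False
    next_state: Optional[str] = None
    fills_gut: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bout", "pause"):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("events must have positive duration")
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.kind == "pause" and self.pause_class is None:
            self.pause_class = "unknown"

    @property
    def rate(self) -> float:
        """Realised feeding rate (g/s); zero for pauses."""
        return self.amount / self.duration if self.kind == "bout" else 0.0

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class FeedingSequence:
    """Ordered, typed event log for one subject over an observation window."""

    subject: str
    events: list
    window: tuple
    x_init: float = 0.0
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.window[1] < self.window[0]:
            raise ValueError("window end before window start")
        last = self.window[0]
        for ev in self.events:
            if ev.start < last - 1e-9:
                raise ValueError(
                    f"events overlap or are out of order at t={ev.start}")
            last = ev.end
        if self.events and self.events[-1].end > self.window[1] + 1e-6:
            raise ValueError("events extend beyond the observation window")

    def bouts(self) -> list:
        return [e for e in self.events if e.kind == "bout"]

    def pauses(self) -> list:
        return [e for e in self.events if e.kind == "pause"]

    @property
    def labelled(self) -> bool:
        return all(p.pause_class in ("S", "L") for p in self.pauses())

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "subject": self.subject, "kind": e.kind, "start_s": e.start,
            "duration_s": e.duration, "amount_g": e.amount,
            "pause_class": e.pause_class or "", "censored": e.censored,
        } for e in self.events]
        return pd.DataFrame(
            rows, columns=["subject", "kind", "start_s", "duration_s",
                           "amount_g", "pause_class", "censored"])

    def concat(self, other: "FeedingSequence") -> "FeedingSequence":
        """Append a sequence whose window starts at this one's end."""
        if abs(other.window[0] - self.window[1]) > 1e-6:
            raise ValueError("windows are not contiguous")
        return FeedingSequence(
            subject=self.subject,
            events=self.events + other.events,
            window=(self.window[0], other.window[1]),
            x_init=self.x_init, condition=self.condition, meta=dict(self.meta))


@dataclass(frozen=True)
class InterventionSpec:
    """Behavioural/experimental modifications applied during simulation.

    refractory:
        Minimum intermeal interval (s).  With ``refractory_mode="max"``
        (default, matching the "access to food is prevented" design) the
        sampled interval is lengthened to at least this value; with
        ``"suppress"`` the meal-initiation hazard is switched off for the
        refractory period and then resumes along the emptying trajectory.
    sham:
        If True, feeding does not fill the gut (intake still recorded).
    schedule:
        Ordered list of (switch time s, ModelParams) pairs; each applies to
        every stochastic draw initiated at or after its switch time.
    """

    refractory: float = 0.0
    refractory_mode: str = "max"
    sham: bool = False
    schedule: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.refractory_mode not in ("max", "suppress"):
            raise ValueError("refractory_mode must be 'max' or 'suppress'")


def termination_probability(x, T1: float, T2: float):
    """Meal-termination probability sigmoid(T1 * (x - T2)) at fullness x."""
    x = np.asarray(x, dtype=float)
    eta = T1 * (x - T2)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    return float(p) if np.ndim(p) == 0 else p


def sample_bout(params: ModelParams, rng: np.random.Generator):
    """One bout: (duration s, rate g/s, amount g).

    Duration ~ Exponential(lambda_F); rate ~ Normal(mu_F, sigma_F) truncated
    below at zero (negative feeding rates are unphysical; the likelihood
    module uses the matching truncated density).
    """
    duration = rng.exponential(1.0 / params.lambda_F)
    while True:
        rate = rng.normal(params.mu_F, params.sigma_F)
        if rate > 0:
            break
    return duration, rate, rate * duration


def sample_imi_duration(x0: float, params: ModelParams, gut: GutModel,
                        rng: np.random.Generator) -> float:
    """Exact intermeal-interval draw from fullness ``x0`` by hazard inversion."""
    e = rng.exponential(1.0)
    return invert_imi_hazard(x0, e, params.L1, params.L2, gut)


def _lookup_params(schedule, t: float, base: ModelParams) -> ModelParams:
    if not schedule:
        return base
    current = base
    for switch_t, p in schedule:
        if t >= switch_t:
            current = p
        else:
            break
    return current


def simulate(params_or_schedule, gut: GutModel, window: tuple,
             x_init: float = 0.0,
             intervention: Optional[InterventionSpec] = None,
             rng: Optional[np.random.Generator] = None,
             subject: str = "sim", condition: str = ""):
    """Simulate one observation window; returns (FeedingSequence, FullnessTrajectory).

    The process starts in state L (no meal in progress) at fullness
    ``x_init`` with a fresh intermeal clock.  Parameter switches apply to
    draws initiated after the switch time; an in-progress interval is never
    resampled.  Events truncated by the window end are emitted with
    ``censored=True``.
    """
    rng = np.random.default_rng() if rng is None else rng
    iv = intervention or InterventionSpec()
    t0, t1 = float(window[0]), float(window[1])
    if t1 < t0:
        raise ValueError("window end before window start")

    if isinstance(params_or_schedule, ModelParams):
        base = params_or_schedule
        schedule = list(iv.schedule) if iv.schedule else []
    else:
        schedule = sorted(params_or_schedule, key=lambda sp: sp[0])
        if not schedule:
            raise ValueError("empty parameter schedule")
        if iv.schedule:
            raise ValueError("schedule given both directly and in the intervention")
        base = schedule[0][1]
    for switch_t, _ in schedule:
        if not (t0 <= switch_t <= t1):
            raise ValueError(f"schedule switch at t={switch_t} outside window")

    events: list = []
    t = t0
    x = float(x_init)
    state = "L"
    had_meal = False  # the refractory period follows meal termination only

    while t < t1:
        p = _lookup_params(schedule, t, base)
        if state == "L":
            refractory = iv.refractory if had_meal else 0.0
            if iv.refractory_mode == "suppress" and refractory > 0:
                xr = empty_fullness(x, refractory, gut)
                dur = refractory + sample_imi_duration(xr, p, gut, rng)
            else:
                dur = sample_imi_duration(x, p, gut, rng)
                dur = max(dur, refractory)
            censored = t + dur > t1
            obs = min(dur, t1 - t)
            if obs > 0:
                events.append(EventRecord(
                    "pause", t, obs, pause_class="L", fullness_at_start=x,
                    censored=censored))
            x = empty_fullness(x, obs, gut)
            t += obs
            state = "F"
        elif state == "S":
            dur = rng.exponential(1.0 / p.lambda_S)
            censored = t + dur > t1
            obs = min(dur, t1 - t)
            if obs > 0:
                events.append(EventRecord(
                    "pause", t, obs, pause_class="S", fullness_at_start=x,
                    censored=censored))
            x = empty_fullness(x, obs, gut)
            t += obs
            state = "F"
        else:  # feeding bout
            dur, rate, _ = sample_bout(p, rng)
            censored = t + dur > t1
            obs = min(dur, t1 - t)
            amount = rate * obs
            if obs > 0:
                ev = EventRecord(
                    "bout", t, obs, amount=amount, fullness_at_start=x,
                    censored=censored, fills_gut=not iv.sham)
                events.append(ev)
            if not iv.sham:
                x += amount
            t += obs
            if censored:
                break
            # meal-termination decision at bout-end fullness
            term = rng.random() < termination_probability(x, p.T1, p.T2)
            state = "L" if term else "S"
            if term:
                had_meal = True
            if obs > 0:
                events[-1].next_state = state

    seq = FeedingSequence(subject=subject, events=events, window=(t0, t1),
                          x_init=x_init, condition=condition)
    traj = fullness_trajectory(seq, gut, x_init)
    return seq, traj


@dataclass
class SequenceSummary:
    """Meal-level observables of one sequence."""

    total_intake: float
    normalised_intake: float  # g per normaliser unit (default: per hour)
    meal_sizes: np.ndarray
    meal_durations: np.ndarray
    imis: np.ndarray
    meal_count: int
    bout_count: int
    mean_bout_duration: float
    mean_bout_rate: float
    hourly_intake: np.ndarray

    def to_dict(self) -> dict:
        return {
            "total_intake_g": float(self.total_intake),
            "normalised_intake": float(self.normalised_intake),
            "meal_count": int(self.meal_count),
            "bout_count": int(self.bout_count),
            "mean_meal_size_g": float(np.mean(self.meal_sizes)) if len(self.meal_sizes) else float("nan"),
            "mean_meal_duration_s": float(np.mean(self.meal_durations)) if len(self.meal_durations) else float("nan"),
            "mean_imi_s": float(np.mean(self.imis)) if len(self.imis) else float("nan"),
            "mean_bout_duration_s": float(self.mean_bout_duration),
            "mean_bout_rate_g_per_s": float(self.mean_bout_rate),
        }


def summarise(seq: FeedingSequence, normaliser_s: float = 3600.0) -> SequenceSummary:
    """Meal-pattern summary (intake, meal sizes/durations, IMIs, counts).

    Meals are maximal runs of bouts and short (S) pauses; the run ends at
    an L pause or the window edge.  Censored events are excluded from
    duration/interval statistics but their intake counts toward totals.
    Requires resolved pause classes.
    """
    for p in seq.pauses():
        if p.pause_class not in ("S", "L"):
            raise ValueError(
                "sequence has unresolved pause classes; run "
                "satiety.io.label_meals first")
    bouts = seq.bouts()
    total = sum(b.amount for b in bouts)
    window_s = seq.window[1] - seq.window[0]
    hours = max(window_s, 1e-12) / 3600.0

    meal_sizes, meal_durations, imis = [], [], []
    cur_size, cur_start, cur_end = 0.0, None, None
    cur_censored = False
    for ev in seq.events:
        if ev.kind == "bout":
            if cur_start is None:
                cur_start = ev.start
            cur_size += ev.amount
            cur_end = ev.end
            cur_censored = cur_censored or ev.censored
        elif ev.pause_class == "S":
            cur_censored = cur_censored or ev.censored
        else:  # L pause closes any open meal
            if cur_start is not None:
                meal_sizes.append(cur_size)
                if not cur_censored:
                    meal_durations.append(cur_end - cur_start)
                cur_size, cur_start, cur_end = 0.0, None, None
                cur_censored = False
            if not ev.censored:
                imis.append(ev.duration)
    if cur_start is not None:
        meal_sizes.append(cur_size)
        if not cur_censored:
            meal_durations.append(cur_end - cur_start)

    complete_bouts = [b for b in bouts if not b.censored]
    edges = np.arange(seq.window[0], seq.window[1] + 3600.0, 3600.0)
    starts = np.array([b.start for b in bouts]) if bouts else np.empty(0)
    amounts = np.array([b.amount for b in bouts]) if bouts else np.empty(0)
    hourly = (np.histogram(starts, bins=edges, weights=amounts)[0]
              if len(edges) > 1 else np.zeros(0))

    return SequenceSummary(
        total_intake=total,
        normalised_intake=total / (window_s / normaliser_s) if window_s > 0 else 0.0,
        meal_sizes=np.asarray(meal_sizes),
        meal_durations=np.asarray(meal_durations),
        imis=np.asarray(imis),
        meal_count=len(meal_sizes),
        bout_count=len(bouts),
        mean_bout_duration=(np.mean([b.duration for b in complete_bouts])
                            if complete_bouts else float("nan")),
        mean_bout_rate=(np.mean([b.rate for b in complete_bouts])
                        if complete_bouts else float("nan")),
        hourly_intake=hourly,
    )
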