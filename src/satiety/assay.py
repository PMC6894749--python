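"""Simplified, regression-based feeding assay (no MCMC).

Pools event data across the animals in a condition and estimates each
behavioural component with a standard fit:

* meal termination — logistic regression of the terminate/continue outcome
  on fullness at bout end; the slope/intercept map back to the sigmoid
  parameters via ``T1 = slope``, ``T2 = -intercept/slope``;
* intermeal interval — ordinary least squares of the interval on fullness
  at meal termination;
* within-bout behaviour — exponential (bout and short-pause durations) and
  normal (feeding rate) maximum-likelihood fits.

Also provides the classical satiety-ratio baseline (first meal size vs the
following intermeal interval) and the model-free moving-window average of
the intermeal interval against fullness, both used to benchmark
fullness-based prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gut import GutModel, empty_fullness
from .simulate import FeedingSequence

__all__ = [
    "pooled_records",
    "fit_termination_logistic",
    "fit_imi_linear",
    "fit_bout_distributions",
    "satiety_ratio",
    "moving_window_imi",
    "PooledAssayResult",
    "run_assay",
]


def pooled_records(sequences: Iterable[FeedingSequence], gut: GutModel) -> pd.DataFrame:
    """Pooled bout-end records across subjects.

    One row per uncensored bout with an observed routing outcome:
    ``fullness`` (g, at bout end, recomputed from the events), ``terminated``
    (1 if the meal ended there), and, where the meal terminated and the
    following intermeal interval is complete, ``imi`` (s).
    """
    rows = []
    for seq in sequences:
        x = float(seq.x_init)
        t = seq.window[0]
        events = seq.events
        for i, ev in enumerate(events):
            if ev.start > t + 1e-12:
                x = empty_fullness(x, ev.start - t, gut)
            if ev.kind == "bout":
                if getattr(ev, "fills_gut", True):
                    x += ev.amount
                if not ev.censored and i + 1 < len(events) and events[i + 1].kind == "pause":
                    nxt = events[i + 1]
                    if nxt.pause_class not in ("S", "L"):
                        raise ValueError("unresolved pause classes; label meals first")
                    terminated = nxt.pause_class == "L"
                    imi = (nxt.duration
                           if terminated and not nxt.censored else np.nan)
                    rows.append({"subject": seq.subject, "fullness": x,
                                 "terminated": int(terminated), "imi": imi})
            else:
                x = empty_fullness(x, ev.duration, gut)
            t = ev.end
    return pd.DataFrame(rows, columns=["subject", "fullness", "terminated", "imi"])


@dataclass
class LogisticTerminationFit:
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    T1: float
    T2: float
    separated: bool
    n: int
    model: object = field(repr=False, default=None)

    def predict(self, fullness):
        eta = self.intercept + self.slope * np.asarray(fullness, float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_termination_logistic(records: pd.DataFrame) -> LogisticTerminationFit:
    """ML logistic fit of meal termination on fullness at bout end.

    Complete separation is flagged and handled with a weak L2 penalty.
    """
    y = np.asarray(records["terminated"], dtype=float)
    x = np.asarray(records["fullness"], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both termination outcomes must be present")
    X = sm.add_constant(x)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.Logit(y, X).fit(disp=0)
            params, bse = res.params, res.bse
        except Exception:
            separated = True
            res = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
            params = res.params
            bse = np.full(2, np.nan)
    intercept, slope = float(params[0]), float(params[1])
    T1 = slope
    T2 = -intercept / slope if slope != 0 else np.nan
    return LogisticTerminationFit(
        intercept=intercept, slope=slope,
        intercept_se=float(bse[0]), slope_se=float(bse[1]),
        T1=T1, T2=T2, separated=separated, n=len(y), model=res)


@dataclass
class LinearIMIFit:
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    r_squared: float
    n: int
    model: object = field(repr=False, default=None)

    def predict(self, fullness):
        return self.intercept + self.slope * np.asarray(fullness, float)


def fit_imi_linear(records: pd.DataFrame) -> LinearIMIFit:
    """OLS of the intermeal interval on fullness at meal termination."""
    df = records.dropna(subset=["imi"])
    if len(df) < 3:
        raise ValueError("need at least 3 complete intermeal intervals")
    X = sm.add_constant(np.asarray(df["fullness"], float))
    res = sm.OLS(np.asarray(df["imi"], float), X).fit()
    return LinearIMIFit(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        intercept_se=float(res.bse[0]), slope_se=float(res.bse[1]),
        r_squared=float(res.rsquared), n=len(df), model=res)


@dataclass
class BoutDistributionFit:
    lambda_F: float
    lambda_S: float
    rate_mean: float
    rate_sd: float
    n_bouts: int
    n_short_pauses: int


def fit_bout_distributions(sequences: Iterable[FeedingSequence]) -> BoutDistributionFit:
    """Pooled exponential/normal ML fits of the within-meal primitives."""
    bd, sd, rates = [], [], []
    for seq in sequences:
        for ev in seq.events:
            if ev.censored:
                continue
            if ev.kind == "bout":
                bd.append(ev.duration)
                if ev.duration > 0:
                    rates.append(ev.amount / ev.duration)
            elif ev.pause_class == "S":
                sd.append(ev.duration)
    bd, sd, rates = map(np.asarray, (bd, sd, rates))
    return BoutDistributionFit(
        lambda_F=1.0 / bd.mean() if len(bd) else np.nan,
        lambda_S=1.0 / sd.mean() if len(sd) else np.nan,
        rate_mean=rates.mean() if len(rates) else np.nan,
        rate_sd=rates.std(ddof=1) if len(rates) > 1 else np.nan,
        n_bouts=len(bd), n_short_pauses=len(sd))


@dataclass
class SatietyRatioResult:
    ratio: float                # s/g: first IMI divided by first meal size
    first_meal_size: float
    first_imi: float
    predictions: pd.DataFrame   # later meals: size, observed IMI, predicted IMI

    @property
    def mean_abs_error(self) -> float:
        d = self.predictions.dropna(subset=["observed_imi"])
        if not len(d):
            return np.nan
        return float(np.mean(np.abs(d["predicted_imi"] - d["observed_imi"])))


def satiety_ratio(seq: FeedingSequence) -> SatietyRatioResult:
    """Classical satiety-ratio baseline.

    The ratio is computed from the FIRST meal and its following intermeal
    interval only (the classical method discards all later meals), oriented
    as interval / meal size (s/g) so that larger means more satiating.
    Every later meal gets a predicted interval of ratio * meal size, paired
    with the observed one for comparison.
    """
    meals = []  # (size, following complete IMI or nan)
    cur_size = 0.0
    open_meal = False
    for ev in seq.events:
        if ev.kind == "bout":
            cur_size += ev.amount
            open_meal = True
        elif ev.pause_class == "L":
            if open_meal:
                meals.append((cur_size, ev.duration if not ev.censored else np.nan))
                cur_size, open_meal = 0.0, False
        elif ev.pause_class not in ("S",):
            raise ValueError("unresolved pause classes; label meals first")
    if open_meal:
        meals.append((cur_size, np.nan))
    if not meals or not np.isfinite(meals[0][1]) or meals[0][0] <= 0:
        raise ValueError("no complete first (meal, intermeal interval) pair")
    size0, imi0 = meals[0]
    ratio = imi0 / size0
    later = meals[1:]
    pred = pd.DataFrame({
        "meal_size": [m[0] for m in later],
        "observed_imi": [m[1] for m in later],
        "predicted_imi": [ratio * m[0] for m in later],
    })
    return SatietyRatioResult(ratio=float(ratio), first_meal_size=float(size0),
                              first_imi=float(imi0), predictions=pred)


def moving_window_imi(records: pd.DataFrame, window_width: Optional[float] = None,
                      min_count: int = 20, n_points: int = 50) -> pd.DataFrame:
    """Moving average of the intermeal interval against fullness.

    A window of width ``window_width`` (default: 10% of the pooled fullness
    range) slides across fullness-at-termination; windows with fewer than
    ``min_count`` records are skipped with a warning.  Returns columns
    (fullness, mean_imi, count).
    """
    df = records.dropna(subset=["imi"])
    if not len(df):
        raise ValueError("no complete intermeal intervals")
    x = np.asarray(df["fullness"], float)
    y = np.asarray(df["imi"], float)
    if len(df) == 1:
        return pd.DataFrame({"fullness": [x[0]], "mean_imi": [y[0]], "count": [1]})
    span = x.max() - x.min()
    if window_width is None:
        window_width = max(0.1 * span, 1e-9)
    centres = np.linspace(x.min(), x.max(), n_points)
    rows = []
    skipped = 0
    min_count = min(min_count, len(df))
    for c in centres:
        mask = np.abs(x - c) <= window_width / 2.0
        if mask.sum() >= min_count:
            rows.append({"fullness": c, "mean_imi": float(y[mask].mean()),
                         "count": int(mask.sum())})
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} moving-window positions skipped "
                      f"(fewer than {min_count} records)")
    return pd.DataFrame(rows, columns=["fullness", "mean_imi", "count"])


@dataclass
class PooledAssayResult:
    termination: LogisticTerminationFit
    imi: LinearIMIFit
    distributions: BoutDistributionFit
    n_records: int

    def implied_params(self) -> dict:
        """Subset of behavioural parameters implied by the pooled fits."""
        return {
            "lambda_F": self.distributions.lambda_F,
            "mu_F": self.distributions.rate_mean,
            "sigma_F": self.distributions.rate_sd,
            "lambda_S": self.distributions.lambda_S,
            "T1": self.termination.T1,
            "T2": self.termination.T2,
            "imi_intercept_s": self.imi.intercept,
            "imi_slope_s_per_g": self.imi.slope,
        }


def run_assay(sequences, gut: GutModel) -> PooledAssayResult:
    """End-to-end MCMC-free assay on pooled labelled sequences."""
    seqs = list(sequences)
    records = pooled_records(seqs, gut)
    return PooledAssayResult(
        termination=fit_termination_logistic(records),
        imi=fit_imi_linear(records),
        distributions=fit_bout_distributions(seqs),
        n_records=len(records))
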