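"""Reading, cleaning and labelling bout-level feeding event logs.

The on-disk dialect is a delimited text table with one row per feeding
bout (the format produced by CLAMS/BioDAQ-style monitors after export):
subject id, bout start, duration (s) and amount (g).  Start times may be
numeric seconds or timestamps.  Inter-bout gaps become pause events of
class "unknown" until :func:`label_meals` resolves them into short
within-meal pauses (S) and intermeal intervals (L).

Cleaning follows the standard monitor-artefact rules: adjacent
equal-magnitude opposite-sign ("cancelling") reading pairs, non-positive
amounts, and amount/rate outliers; every drop is itemised in a
CleaningReport and cleaning is idempotent.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .gut import GutModel
from .hierarchical import HyperPriorConfig
from .params import ModelParams
from .simulate import EventRecord, FeedingSequence

__all__ = [
    "BoutFileDialect",
    "CleaningReport",
    "read_bout_events",
    "write_bout_events",
    "clean_events",
    "label_meals",
    "split_pause_threshold",
    "save_params",
    "load_params",
    "save_gut",
    "load_gut",
    "save_hyper",
    "load_hyper",
]

DEFAULT_K = 0.00055  # emptying constant fitted for male Wistar rats


@dataclass(frozen=True)
class BoutFileDialect:
    """Column naming and parsing conventions for bout CSV files."""

    subject_col: str = "subject"
    start_col: str = "start_s"
    duration_col: str = "duration_s"
    amount_col: str = "amount_g"
    delimiter: str = ","
    timestamp_format: Optional[str] = None  # None -> numeric seconds
    lights_on: str = "06:00"
    lights_off: str = "18:00"

    @property
    def required(self) -> tuple:
        return (self.subject_col, self.start_col, self.duration_col,
                self.amount_col)


def read_bout_events(path, dialect: BoutFileDialect = BoutFileDialect(),
                     window: Optional[tuple] = None) -> list:
    """Read a bout file into one FeedingSequence per subject.

    Inter-bout gaps become pauses of class "unknown"; the window defaults
    to the file's time span per subject.  Unparseable rows are collected
    and reported in a single warning, never silently dropped.
    """
    df = pd.read_csv(path, sep=dialect.delimiter)
    missing = [c for c in dialect.required if c not in df.columns]
    if missing:
        raise ValueError(f"bout file is missing required columns: {missing}")
    if df.empty:
        return []

    bad_rows = []
    if dialect.timestamp_format is not None:
        ts = pd.to_datetime(df[dialect.start_col],
                            format=dialect.timestamp_format, errors="coerce")
        origin = ts.min()
        start = (ts - origin).dt.total_seconds()
    else:
        start = pd.to_numeric(df[dialect.start_col], errors="coerce")
    dur = pd.to_numeric(df[dialect.duration_col], errors="coerce")
    amt = pd.to_numeric(df[dialect.amount_col], errors="coerce")
    ok = start.notna() & dur.notna() & amt.notna() & (dur > 0)
    bad_rows = df.index[~ok].tolist()
    if bad_rows:
        warnings.warn(f"{len(bad_rows)} unparseable rows skipped "
                      f"(indices {bad_rows[:10]}{'...' if len(bad_rows) > 10 else ''})")
    df = df.loc[ok].assign(_start=start[ok], _dur=dur[ok], _amt=amt[ok])

    sequences = []
    for subject, grp in df.groupby(dialect.subject_col, sort=True):
        grp = grp.sort_values("_start")
        win = window or (float(grp["_start"].iloc[0]),
                         float((grp["_start"] + grp["_dur"]).iloc[-1]))
        events = []
        prev_end = None
        for _, row in grp.iterrows():
            s, d, a = float(row["_start"]), float(row["_dur"]), float(row["_amt"])
            if prev_end is not None and s > prev_end + 1e-9:
                events.append(EventRecord("pause", prev_end, s - prev_end,
                                          pause_class="unknown"))
            events.append(EventRecord("bout", s, d, amount=max(a, 0.0),
                                      pause_class=None))
            # keep raw (possibly negative) amount for the cleaning stage
            events[-1].amount_raw = a
            prev_end = s + d
        seq = FeedingSequence(subject=str(subject), events=events, window=win)
        seq.meta["source"] = str(path)
        seq.meta["input_sha1"] = _file_sha1(path)
        sequences.append(seq)
    return sequences


def _file_sha1(path) -> str:
    try:
        return hashlib.sha1(Path(path).read_bytes()).hexdigest()[:12]
    except (OSError, TypeError):
        return ""


def write_bout_events(sequences: Iterable[FeedingSequence], path,
                      dialect: BoutFileDialect = BoutFileDialect()) -> None:
    """Write bout events (pauses are implicit gaps) in the bout-CSV dialect."""
    rows = []
    for seq in sequences:
        for b in seq.bouts():
            rows.append({dialect.subject_col: seq.subject,
                         dialect.start_col: b.start,
                         dialect.duration_col: b.duration,
                         dialect.amount_col: b.amount})
    pd.DataFrame(rows, columns=list(BoutFileDialect().required)).to_csv(
        path, sep=dialect.delimiter, index=False)


@dataclass
class CleaningReport:
    input_count: int
    cancelling_pairs: int = 0
    non_positive: int = 0
    amount_outliers: int = 0
    rate_outliers: int = 0

    @property
    def dropped(self) -> int:
        return (2 * self.cancelling_pairs + self.non_positive
                + self.amount_outliers + self.rate_outliers)

    @property
    def retained(self) -> int:
        return self.input_count - self.dropped

    @property
    def retained_fraction(self) -> float:
        return self.retained / self.input_count if self.input_count else 1.0

    def to_dict(self) -> dict:
        return {**asdict(self), "dropped": self.dropped,
                "retained": self.retained,
                "retained_fraction": self.retained_fraction}


@dataclass(frozen=True)
class CleaningRules:
    """Configurable artefact-removal bounds (amounts in g, rates in g/s)."""

    max_amount: float = 10.0
    max_rate: float = 0.2
    min_amount: float = 0.0  # exclusive
    cancel_tol: float = 1e-9


def clean_events(sequences: Iterable[FeedingSequence],
                 rules: CleaningRules = CleaningRules()):
    """Remove monitor artefacts from bout logs.

    Applied per subject, in order: adjacent equal-magnitude opposite-sign
    bout pairs (both dropped as a cancelling sensor artefact), non-positive
    amounts, then amount/implied-rate outliers.  Pauses are rebuilt from
    the surviving bouts.  Returns (cleaned sequences, CleaningReport).
    Never raises on content.
    """
    total_report = CleaningReport(input_count=0)
    cleaned = []
    for seq in sequences:
        bouts = [(b.start, b.duration, getattr(b, "amount_raw", b.amount))
                 for b in seq.bouts()]
        total_report.input_count += len(bouts)

        keep = [True] * len(bouts)
        i = 0
        while i < len(bouts) - 1:
            a0, a1 = bouts[i][2], bouts[i + 1][2]
            if (keep[i] and keep[i + 1] and a0 * a1 < 0
                    and abs(a0 + a1) <= rules.cancel_tol):
                keep[i] = keep[i + 1] = False
                total_report.cancelling_pairs += 1
                i += 2
            else:
                i += 1
        bouts = [b for b, k in zip(bouts, keep) if k]

        kept = []
        for s, d, a in bouts:
            if a <= rules.min_amount:
                total_report.non_positive += 1
            elif a > rules.max_amount:
                total_report.amount_outliers += 1
            elif d > 0 and a / d > rules.max_rate:
                total_report.rate_outliers += 1
            else:
                kept.append((s, d, a))

        events = []
        prev_end = None
        for s, d, a in kept:
            if prev_end is not None and s > prev_end + 1e-9:
                events.append(EventRecord("pause", prev_end, s - prev_end,
                                          pause_class="unknown"))
            events.append(EventRecord("bout", s, d, amount=a))
            prev_end = s + d
        out = FeedingSequence(subject=seq.subject, events=events,
                              window=seq.window, x_init=seq.x_init,
                              condition=seq.condition, meta=dict(seq.meta))
        out.meta["cleaning_rules"] = asdict(rules)
        cleaned.append(out)
    return cleaned, total_report


def label_meals(seq: FeedingSequence, criterion: float | str = 300.0):
    """Resolve unknown pauses into short (S) / intermeal (L) classes.

    ``criterion`` is either a threshold in seconds (pauses >= threshold
    become intermeal intervals) or ``"mixture"``, which fits a
    two-component Gaussian mixture to log-duration and splits at the
    posterior crossover.  The default 300 s is a meal-definition convention
    of the field, not a property of the model; downstream estimates of
    lambda_S, T1, T2, L1 and L2 depend on it, so the criterion used is
    recorded in the sequence metadata.
    """
    pauses = [p for p in seq.pauses()]
    durations = np.array([p.duration for p in pauses if p.pause_class == "unknown"])
    if isinstance(criterion, str):
        if criterion != "mixture":
            raise ValueError("criterion must be a threshold (s) or 'mixture'")
        threshold = split_pause_threshold(durations)
    else:
        threshold = float(criterion)
    events = []
    for ev in seq.events:
        if ev.kind == "pause" and ev.pause_class == "unknown":
            cls = "L" if ev.duration >= threshold else "S"
            ev2 = EventRecord("pause", ev.start, ev.duration,
                              pause_class=cls, censored=ev.censored,
                              fullness_at_start=ev.fullness_at_start)
            events.append(ev2)
        else:
            events.append(ev)
    out = FeedingSequence(subject=seq.subject, events=events, window=seq.window,
                          x_init=seq.x_init, condition=seq.condition,
                          meta=dict(seq.meta))
    out.meta["meal_criterion_s"] = threshold
    out.meta["meal_criterion_kind"] = ("mixture" if criterion == "mixture"
                                       else "threshold")
    return out


def split_pause_threshold(durations_s: np.ndarray) -> float:
    """Crossover of a 2-component normal mixture on log pause duration.

    The crossover (equal posterior responsibility) always falls between the
    two component means; used as a data-driven meal criterion.
    """
    from sklearn.mixture import GaussianMixture

    d = np.asarray(durations_s, float)
    d = d[d > 0]
    if len(d) < 10:
        raise ValueError("need at least 10 pauses for a mixture criterion")
    logd = np.log(d).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(logd)
    means = np.sort(gm.means_.ravel())
    grid = np.linspace(means[0], means[1], 2001)
    post = gm.predict_proba(grid.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    diff = post[:, order[1]] - post[:, order[0]]
    idx = int(np.argmin(np.abs(diff)))
    return float(np.exp(grid[idx]))


# ---------------------------------------------------------------------------
# parameter / config JSON round-trips
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def _dump(path, kind: str, payload: dict, provenance: Optional[dict] = None):
    doc = {"schema_version": _SCHEMA_VERSION, "kind": kind, **payload}
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def _load(path, kind: str) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != kind:
        raise ValueError(f"{path}: expected kind={kind!r}, got {doc.get('kind')!r}")
    return doc


def save_params(params: ModelParams, path) -> None:
    _dump(path, "model_params", {"params": params.to_dict()})


def load_params(path) -> ModelParams:
    doc = _load(path, "model_params")
    try:
        return ModelParams.from_dict(doc["params"])
    except (KeyError, ValueError) as e:
        raise ValueError(f"{path}: invalid model parameters: {e}") from e


def save_gut(gut: GutModel, path) -> None:
    _dump(path, "gut_model", {"gut": asdict(gut)})


def load_gut(path) -> GutModel:
    doc = _load(path, "gut_model")
    g = dict(doc.get("gut", {}))
    provenance = {}
    if "k" not in g:
        g["k"] = DEFAULT_K
        provenance["k"] = "absent in file; default 0.00055 injected"
    try:
        gut = GutModel(**g)
    except (TypeError, ValueError) as e:
        raise ValueError(f"{path}: invalid gut model: {e}") from e
    if provenance:
        warnings.warn(f"{path}: {provenance['k']}")
    return gut


def save_hyper(hyper: HyperPriorConfig, path) -> None:
    _dump(path, "hyper_prior", {"hyper": {
        "mu_star": list(hyper.mu_star), "mu_prior_sd": hyper.mu_prior_sd,
        "tau_scale": hyper.tau_scale, "lkj_eta": hyper.lkj_eta}})


def load_hyper(path) -> HyperPriorConfig:
    doc = _load(path, "hyper_prior")
    h = doc.get("hyper", {})
    try:
        return HyperPriorConfig(
            mu_star=tuple(h["mu_star"]), mu_prior_sd=h["mu_prior_sd"],
            tau_scale=h["tau_scale"], lkj_eta=h["lkj_eta"])
    except (KeyError, ValueError) as e:
        raise ValueError(f"{path}: invalid hyperprior config: {e}") from e
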