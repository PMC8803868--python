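"""Behavioral readouts: balance index time courses and wheel-training metrics.

The balance index (BI) of a force-corridor crossing is the log10 ratio of the
integrated force signals from the left and right sides of the body; a session
datapoint is the mean over at least three valid trials (trials with fewer
than five strides are discarded upstream).  BI time courses are
baseline-normalised and summarised by the BI nearest day 15 and by the
trapezoidal areas under the curve over early, late and adapted post-surgery
phases.  Wheel training is summarised by the total distance run and the OLS
slope of distance across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

#: default post-surgery phase windows in days, half-open [start, end)
PHASES_FIGURE = {"early": (0.0, 9.0), "late": (9.0, 21.0), "adapted": (21.0, np.inf)}
#: alternative windows used for the cumulative-imbalance text values
PHASES_METHODS = {"early": (0.0, 4.0), "late": (4.0, 21.0), "adapted": (21.0, np.inf)}

MIN_STRIDES = 5
MIN_TRIALS = 3


@dataclass
class BalanceTrial:
    """One corridor crossing: integrated left/right force and stride count."""

    left_integral: float
    right_integral: float
    n_strides: int = MIN_STRIDES

    @property
    def valid(self) -> bool:
        return (
            self.left_integral > 0
            and self.right_integral > 0
            and self.n_strides >= MIN_STRIDES
        )

    @property
    def bi(self) -> float:
        return float(np.log10(self.left_integral / self.right_integral))


@dataclass
class BehaviorRecord:
    """Wheel-session series or a balance-index time course for one animal."""

    subject: str = ""
    condition: str = ""
    days: np.ndarray | None = None           # BI time course sampling days
    bi: np.ndarray | None = None             # BI per day (raw, not normalised)
    baseline: float = 0.0                    # pre-surgery mean BI
    sessions: np.ndarray | None = None       # wheel session indices
    distances: np.ndarray | None = None      # metres per session

    def __post_init__(self) -> None:
        for name in ("days", "bi", "sessions", "distances"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.days is not None and np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.sessions is not None and np.any(np.diff(self.sessions) <= 0):
            raise ValueError("sessions must be strictly increasing")


def balance_index(trials: Sequence[BalanceTrial]) -> float:
    """Session balance index: mean per-trial log10(∫left/∫right).

    Trials with nonpositive integrals or fewer than five strides are
    rejected; fewer than three valid trials gives NaN (missing datapoint).
    """
    vals = [t.bi for t in trials if t.valid]
    if len(vals) < MIN_TRIALS:
        return float("nan")
    return float(np.mean(vals))


def _trapz_window(days: np.ndarray, values: np.ndarray, start: float, end: float) -> float:
    """Trapezoidal integral over [start, end), interpolating the endpoints."""
    hi = min(end, days[-1])
    lo = max(start, days[0])
    if hi <= lo:
        raise ValueError(f"phase window [{start}, {end}) not covered by the time course")
    pts = days[(days > lo) & (days < hi)]
    grid = np.concatenate([[lo], pts, [hi]])
    vals = np.interp(grid, days, values)
    return float(np.trapezoid(vals, grid))


def bi_features(
    record: BehaviorRecord,
    baseline: float | None = None,
    phases: dict = PHASES_FIGURE,
) -> dict:
    """BI_day15 and phase AUCs of a baseline-normalised BI time course.

    Values are baseline-subtracted; AUCs use the trapezoidal rule over the
    measured days inside each half-open phase window, and BI_day15 is the
    normalised value at the measurement nearest day 15.
    """
    if record.days is None or record.bi is None:
        raise ValueError("record has no BI time course")
    b = record.baseline if baseline is None else baseline
    days = record.days
    norm = record.bi - b
    out = {"bi_day15": float(norm[np.argmin(np.abs(days - 15.0))])}
    for name, (start, end) in phases.items():
        out[f"auc_{name}"] = _trapz_window(days, norm, start, min(end, days[-1]))
    return out


def wheel_metrics(record: BehaviorRecord) -> dict:
    """Total distance (m) and OLS slope of distance vs session (m/session)."""
    if record.distances is None:
        raise ValueError("record has no wheel sessions")
    d = record.distances
    if d.size < 2:
        raise ValueError("need at least 2 sessions for a slope")
    x = record.sessions if record.sessions is not None else np.arange(d.size, dtype=float)
    slope = stats.linregress(x, d).slope
    return {"total_distance": float(d.sum()), "slope": float(slope)}


def logistic_training_curve(sessions, distances):
    """Convenience logistic fit of group distance vs session (display only).

    Returns ``(params, fitted)`` with params = (L, k, x0) of
    L / (1 + exp(-k (x - x0))).  Untested display helper.
    """
    from scipy.optimize import curve_fit

    x = np.asarray(sessions, dtype=float)
    y = np.asarray(distances, dtype=float)

    def f(x, L, k, x0):
        return L / (1.0 + np.exp(-k * (x - x0)))

    p0 = (y.max() if y.max() > 0 else 1.0, 0.5, np.median(x))
    params, _ = curve_fit(f, x, y, p0=p0, maxfev=10000)
    return params, f(x, *params)
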