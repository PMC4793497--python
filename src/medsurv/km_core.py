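"""Kaplan–Meier product-limit estimation on a single right-censored sample.

A sample is a pair of equal-length vectors: observed times Z = min(X, Y) and
event indicators delta = 1{X <= Y}, where X is the latent survival time and Y
the censoring time.  This module fits the product-limit survival curve,
evaluates it (right-continuously) at arbitrary times, computes the Greenwood
variance of the survival estimate, extracts the median survival time
theta = inf{t : S(t) <= 0.5}, and locates the uncensored time closest to a
reference point — the building block of the composite variance used by the
median test.

Conventions (all standard, stated once because file formats and papers vary):

* delta = 1 means the event was observed; delta = 0 means right-censored.
* When an event and a censoring share a time, the event happens first: a
  subject censored at t is still at risk for events at t.
* The curve is right-continuous: S evaluated AT an event time includes that
  jump, so the median lands on an event time.
* Times may be any finite reals; shifted families with large offsets are fine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Optional, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "fit_km",
    "km_survival_at",
    "greenwood_variance_at",
    "km_median",
    "closest_uncensored_time",
]

# Slack for "survival <= 0.5" so that cumulative products that are exactly
# one half in real arithmetic (e.g. fully uncensored even n) are not pushed
# past the median by floating-point rounding.
_MEDIAN_TOL = 1e-12


@dataclass
class SurvivalSample:
    """One group's right-censored observations.

    Parameters
    ----------
    times : array-like of float
        Observed times Z_j = min(X_j, Y_j).  Any finite reals.
    events : array-like of {0, 1}
        delta_j = 1 if the event was observed at Z_j, 0 if censored.
    label : hashable, optional
        Opaque group identifier carried through to results.
    """

    times: np.ndarray
    events: np.ndarray
    label: Hashable = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        if self.times.ndim != 1 or self.events.ndim != 1:
            raise InvalidInputError("times and events must be 1-dimensional")
        if self.times.size == 0:
            raise InvalidInputError("empty sample")
        if self.times.shape != self.events.shape:
            raise InvalidInputError(
                f"times (n={self.times.size}) and events (n={self.events.size}) "
                "must have equal length"
            )
        if not np.all(np.isfinite(self.times)):
            raise InvalidInputError("times must be finite")
        ev = np.unique(self.events)
        if not np.all(np.isin(ev, (0, 1))):
            raise InvalidInputError(f"event indicators must be 0 or 1, got {ev}")
        self.events = self.events.astype(np.int8)

    @property
    def n(self) -> int:
        return self.times.size

    def uncensored_times(self) -> np.ndarray:
        """Distinct observed event times, sorted ascending."""
        return np.unique(self.times[self.events == 1])


@dataclass
class KMCurve:
    """Product-limit survival step function with Greenwood bookkeeping.

    ``event_times`` are the distinct times with at least one event;
    ``surv_probs[j]`` is the survival estimate immediately after (and at)
    ``event_times[j]``; ``greenwood_cum[j]`` is the cumulative sum
    sum_{k<=j} d_k / (n_k (n_k - d_k)) feeding the Greenwood variance.
    """

    event_times: np.ndarray
    surv_probs: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_cum: np.ndarray
    n_total: int
    label: Hashable = field(default=None)

    def survival_at(self, t: float) -> float:
        return km_survival_at(self, t)

    def variance_at(self, t: float) -> float:
        return greenwood_variance_at(self, t)

    @property
    def median(self) -> Optional[float]:
        return km_median(self)


def fit_km(sample: SurvivalSample) -> KMCurve:
    """Fit the Kaplan–Meier product-limit estimator.

    At each distinct event time t_j the at-risk count n_j is the number of
    observations with Z >= t_j (ties between events and censorings resolved
    with events first) and d_j the number of events at t_j; the survival
    estimate is the running product of (1 - d_j / n_j).
    """
    t = sample.uncensored_times()
    z_sorted = np.sort(sample.times)
    ev_sorted = np.sort(sample.times[sample.events == 1])

    at_risk = sample.n - np.searchsorted(z_sorted, t, side="left")
    d = (
        np.searchsorted(ev_sorted, t, side="right")
        - np.searchsorted(ev_sorted, t, side="left")
    )
    surv = np.cumprod(1.0 - d / at_risk)
    # Where d == n the survival hits zero and the Greenwood term 1/(n-d) is
    # undefined; the term is dropped — any variance evaluated there is zero
    # anyway because the S(t)^2 factor vanishes.
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(d < at_risk, d / (at_risk * (at_risk - d)), 0.0)
    return KMCurve(
        event_times=t,
        surv_probs=surv,
        at_risk=at_risk.astype(np.int64),
        n_events=d.astype(np.int64),
        greenwood_cum=np.cumsum(terms),
        n_total=sample.n,
        label=sample.label,
    )


def _step_index(curve: KMCurve, t: float) -> int:
    """Index of the largest event time <= t, or -1 if t precedes all jumps."""
    return int(np.searchsorted(curve.event_times, t, side="right")) - 1


def km_survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous evaluation of the survival curve at time ``t``."""
    j = _step_index(curve, t)
    return 1.0 if j < 0 else float(curve.surv_probs[j])


def greenwood_variance_at(curve: KMCurve, t: float) -> float:
    """Greenwood variance estimate S(t)^2 * sum_{t_j <= t} d_j/(n_j(n_j-d_j))."""
    j = _step_index(curve, t)
    if j < 0:
        return 0.0
    s = float(curve.surv_probs[j])
    return s * s * float(curve.greenwood_cum[j])


def km_median(curve: KMCurve) -> Optional[float]:
    """Median survival time, the smallest event time with S(t) <= 0.5.

    Returns ``None`` when the curve never reaches 0.5 (heavy censoring or a
    curve with no events); callers must treat that as a reportable condition,
    not a number.
    """
    below = np.nonzero(curve.surv_probs <= 0.5 + _MEDIAN_TOL)[0]
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


def closest_uncensored_time(
    sample: SurvivalSample, ref: float
) -> Optional[float]:
    """The distinct uncensored time nearest to ``ref``, excluding ``ref`` itself.

    Exact distance ties break toward the smaller time.  Returns ``None`` when
    the sample has no uncensored time other than ``ref`` — the degenerate case
    in which the variance correction term cannot be formed.
    """
    u = sample.uncensored_times()
    u = u[u != ref]
    if u.size == 0:
        return None
    # u is sorted, so argmin takes the first (smaller) time on a distance tie
    return float(u[np.argmin(np.abs(u - ref))])
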