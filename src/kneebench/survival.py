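"""Product-limit estimation of net failure with Greenwood variance.

Net failure is 1 minus the Kaplan-Meier survival estimate, treating death
and end-of-study as ordinary censoring.  It estimates the revision-time
distribution in a hypothetical world without competing death, which is
the appropriate quantity when the *risk* of revision is of interest
(as opposed to the real-world probability of undergoing one).

Conventions
-----------
* At tied times, revisions (events) are processed before censorings —
  the standard product-limit convention.
* Greenwood's variance, evaluated on the survival scale, applies
  unchanged to the failure scale: Var(1 - S) = Var(S).
* Between event times both the failure estimate and its Greenwood SE are
  step functions, carried forward from the last event.
* If the at-risk set is exhausted by events (S reaches 0) the Greenwood
  sum truncates at the last term with ``n_i > d_i`` and failure is
  exactly 1 thereafter.
* Zero follow-up times (same-day revisions) are shifted to a small
  positive epsilon, one day by default, so every event time is strictly
  positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # sklearn-style estimator facade; core functions below are plain numpy
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

__all__ = [
    "DAY",
    "RiskTable",
    "KMEstimate",
    "build_risk_table",
    "km_failure",
    "at_risk",
    "KaplanMeierFailure",
]

#: One day on the year scale; the default zero-time shift.
DAY = 1.0 / 365.25


@dataclass(frozen=True, slots=True)
class RiskTable:
    """Event-time risk sets for one construct within one stratum.

    ``event_times`` are the strictly increasing times with at least one
    revision; ``d`` the revisions at each, ``c`` the censorings in the
    half-open interval between that event time and the next (censorings
    before the first event time are folded into the at-risk counts), and
    ``n`` the number at risk just before each event time.
    """

    event_times: np.ndarray
    d: np.ndarray
    c: np.ndarray
    n: np.ndarray
    n_total: int
    max_time: float
    censor_times: np.ndarray  # sorted raw censoring times; keeps at-risk exact

    def __post_init__(self) -> None:
        if not (len(self.event_times) == len(self.d) == len(self.c) == len(self.n)):
            raise ValueError("risk table columns must have equal length")
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.d < 1):
            raise ValueError("every listed event time must have d >= 1")
        if np.any(np.diff(self.n) > -self.d[:-1] + 1e-9):
            # n[i+1] <= n[i] - d[i]
            raise ValueError("at-risk counts must drop by at least d at each event")

    def __len__(self) -> int:
        return len(self.event_times)


@dataclass(frozen=True, slots=True)
class KMEstimate:
    """Net failure at one evaluation time.

    ``failure`` is F(t) = 1 - S(t) as a proportion, ``gse`` its Greenwood
    standard error on the same scale.  ``n_at_risk_at_t`` counts
    procedures still under observation at the start of ``t`` (observed
    time >= t).  ``extrapolated`` flags an evaluation time beyond the
    last observed follow-up, where the estimate is carried forward from
    the last observation rather than extrapolated.
    """

    t: float
    failure: float
    gse: float
    n_at_risk_at_t: int
    n_events_by_t: int
    extrapolated: bool = False

    @property
    def failure_pct(self) -> float:
        return 100.0 * self.failure

    @property
    def gse_pct(self) -> float:
        return 100.0 * self.gse


def _clean_times(time_years, event_observed, zero_shift: float = DAY):
    t = np.asarray(time_years, dtype=float)
    e = np.asarray(event_observed, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("time and event arrays must have the same shape")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("follow-up times must be finite and non-negative")
    if zero_shift and np.any(t == 0):
        t = t.copy()
        t[t == 0] = zero_shift
    return t, e


def build_risk_table(time_years, event_observed, *, zero_shift: float = DAY) -> RiskTable:
    """Tabulate risk sets from per-procedure times and event indicators.

    Parameters
    ----------
    time_years : array-like of float
        Observed follow-up, years from the primary operation.
    event_observed : array-like of bool
        True where follow-up ended in revision; False for death or
        administrative censoring.
    zero_shift : float
        Times equal to zero are shifted to this value (default one day)
        so that event times are strictly positive; pass 0 to disable.

    Ties between revisions and censorings at the same time are resolved
    with revisions first, so a procedure censored at an event time still
    counts in that event's risk set.
    """
    t, e = _clean_times(time_years, event_observed, zero_shift)
    n_total = t.size
    if n_total == 0:
        z = np.zeros(0)
        return RiskTable(z, z.astype(int), z.astype(int), z.astype(int), 0, 0.0, z)

    event_times, d = np.unique(t[e], return_counts=True)
    cens = np.sort(t[~e])
    # at risk just before time s: observed time >= s (events at s included,
    # censorings at s included because events precede censorings)
    t_sorted = np.sort(t)
    n = n_total - np.searchsorted(t_sorted, event_times, side="left")
    # censorings bucketed into [event_time_i, event_time_{i+1})
    if event_times.size:
        c = np.diff(np.searchsorted(cens, np.concatenate([event_times, [np.inf]]), side="left"))
    else:
        c = np.zeros(0, dtype=int)
    return RiskTable(event_times, d.astype(int), c, n, int(n_total), float(t.max()), cens)


def _km_at(table: RiskTable, t: float) -> tuple[float, float, int]:
    """(failure, gse, events-by-t) at time t from a risk table."""
    k = int(np.searchsorted(table.event_times, t, side="right"))
    if k == 0:
        return 0.0, 0.0, 0
    d = table.d[:k].astype(float)
    n = table.n[:k].astype(float)
    surv = float(np.prod(1.0 - d / n))
    ok = n > d  # Greenwood sum truncates where the risk set is exhausted
    gsum = float(np.sum(d[ok] / (n[ok] * (n[ok] - d[ok]))))
    gse = surv * np.sqrt(gsum)
    return 1.0 - surv, gse, int(d.sum())


def km_failure(table: RiskTable, t: float) -> KMEstimate:
    """Net failure F(t) = 1 - prod_{t_i <= t} (1 - d_i/n_i), with Greenwood SE.

    For ``t`` beyond the last observed follow-up the estimate at the last
    observed time is returned with ``extrapolated=True``; the curve is
    never extended past the data.
    """
    if t <= 0:
        raise ValueError("evaluation time must be positive")
    if len(table) == 0 and table.n_total == 0:
        return KMEstimate(t=t, failure=0.0, gse=0.0, n_at_risk_at_t=0, n_events_by_t=0)
    extrapolated = t > table.max_time
    t_eval = min(t, table.max_time)
    failure, gse, n_events = _km_at(table, t_eval)
    return KMEstimate(
        t=t,
        failure=failure,
        gse=gse,
        n_at_risk_at_t=_at_risk_from_table(table, t),
        n_events_by_t=n_events,
        extrapolated=bool(extrapolated),
    )


def _at_risk_from_table(table: RiskTable, t: float) -> int:
    """n_total minus events and censorings strictly before t."""
    k = int(np.searchsorted(table.event_times, t, side="left"))
    events_before = int(table.d[:k].sum())
    cens_before = int(np.searchsorted(table.censor_times, t, side="left"))
    return table.n_total - events_before - cens_before


def at_risk(time_years, t: float) -> int:
    """Number of procedures with observed time >= t.

    A procedure revised, dead or censored exactly at ``t`` counts as at
    risk at the start of ``t`` (boundary included), matching the number
    remaining at risk at the beginning of the time point of interest.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    return int(np.sum(np.asarray(time_years, dtype=float) >= t))


class KaplanMeierFailure(BaseEstimator):
    """Kaplan-Meier net-failure estimator (sklearn-style).

    Fits the product-limit estimator to one group's follow-up data and
    exposes failure, Greenwood SE and at-risk counts at arbitrary times.

    Parameters
    ----------
    duration_col, event_col : str
        Column names used when ``fit`` is given a DataFrame.
    zero_shift : float
        Shift applied to zero follow-up times (default one day in years).

    Attributes
    ----------
    risk_table_ : RiskTable
        Event times, revisions, censorings and at-risk counts.
    durations_ : ndarray
        Cleaned follow-up times (after the zero shift).
    n_ : int
        Number of procedures fitted.

    Examples
    --------
    >>> km = KaplanMeierFailure().fit([1., 2., 3.], [True, False, True])
    >>> round(km.failure_at(3).failure, 3)
    0.625
    """

    def __init__(self, duration_col: str = "time_years", event_col: str = "event",
                 zero_shift: float = DAY):
        self.duration_col = duration_col
        self.event_col = event_col
        self.zero_shift = zero_shift

    def fit(self, X, y=None):
        """Fit to durations and event indicators.

        ``X`` may be a DataFrame carrying ``duration_col`` and
        ``event_col`` (event given either as booleans or as the strings
        revision/death/administrative), or an array of durations with
        ``y`` the boolean event indicator.
        """
        if hasattr(X, "columns"):
            durations = np.asarray(X[self.duration_col], dtype=float)
            ev = X[self.event_col]
            if ev.dtype == bool:
                events = ev.to_numpy()
            else:
                events = (ev.astype(str) == "revision").to_numpy()
        else:
            durations = np.asarray(X, dtype=float).ravel()
            if y is None:
                raise ValueError("event indicator required when X is an array")
            events = np.asarray(y, dtype=bool).ravel()
        t, e = _clean_times(durations, events, self.zero_shift)
        self.durations_ = t
        self.events_ = e
        self.n_ = int(t.size)
        self.risk_table_ = build_risk_table(t, e, zero_shift=0.0)
        return self

    def failure_at(self, t: float) -> KMEstimate:
        """Net failure, Greenwood SE and at-risk count at time t."""
        return km_failure(self.risk_table_, t)

    def predict(self, T):
        """Failure proportion at each time in ``T`` (curve lookup)."""
        T = np.atleast_1d(np.asarray(T, dtype=float))
        return np.array([km_failure(self.risk_table_, float(t)).failure for t in T])
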