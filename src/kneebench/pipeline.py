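"""Stratified benchmarking pipeline.

Runs the full analysis over every (stratum, timepoint) cell: fit the
product-limit net-failure estimator per construct, select the in-stratum
benchmark, compare every sufficiently-observed construct against it, and
summarise the classification counts.  A historical-benchmark sensitivity
analysis re-runs the comparisons at earlier timepoints against the
construct that is best at a late anchor time (10 years by default),
quantifying how much of "inferiority" is just temporal improvement of
the contemporary benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .benchmark import (
    ComparisonResult,
    NoBenchmarkAvailable,
    Status,
    compare,
    select_benchmark,
)
from .registry import ConstructKey, Stratum, stratum_mask
from .survival import KaplanMeierFailure, KMEstimate

logger = logging.getLogger("kneebench")

__all__ = [
    "AnalysisConfig",
    "SummaryCounts",
    "StratumReport",
    "default_strata",
    "run_analysis",
    "run_sensitivity",
    "summarise_counts",
    "StratifiedBenchmarkAnalysis",
]

_CONSTRUCT_COLS = ["brand", "fixation", "constraint", "bearing", "klass"]


def default_strata() -> tuple[Stratum, ...]:
    """All procedures; by gender; by gender x age band (nine cells)."""
    out = [Stratum()]
    for g in ("male", "female"):
        out.append(Stratum(gender=g))
    for g in ("male", "female"):
        for band in ("under55", "from55to75", "over75"):
            out.append(Stratum(gender=g, age_band=band))
    return tuple(out)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the benchmarking analysis.

    ``benchmark_min_at_risk`` is the eligibility floor for the reference
    construct; ``figure_threshold`` and ``table_threshold`` are the
    at-risk floors for inclusion in graphical summaries and in tabular
    output respectively, ordered table <= figure <= benchmark.
    """

    timepoints: tuple[float, ...] = (3.0, 5.0, 7.0, 10.0)
    benchmark_min_at_risk: int = 1000
    figure_threshold: int = 500
    table_threshold: int = 250
    margins: tuple[float, float] = (0.20, 1.00)
    strata: tuple[Stratum, ...] = field(default_factory=default_strata)
    sensitivity_benchmark_time: float | None = 10.0
    integer_ages: bool = False

    def __post_init__(self) -> None:
        if not (self.table_threshold <= self.figure_threshold <= self.benchmark_min_at_risk):
            raise ValueError("thresholds must satisfy table <= figure <= benchmark_min_at_risk")
        tp = tuple(float(t) for t in self.timepoints)
        if any(b <= a for a, b in zip(tp, tp[1:])) or not tp:
            raise ValueError("timepoints must be non-empty and strictly increasing")
        object.__setattr__(self, "timepoints", tp)
        object.__setattr__(self, "strata", tuple(self.strata))


@dataclass(frozen=True, slots=True)
class SummaryCounts:
    """Classification tallies over comparisons meeting an at-risk floor.

    ``n_constructs`` counts the benchmark itself as one of the constructs
    in use, while the status tallies cover comparators only, so the four
    status counts sum to ``n_constructs - 1`` when a benchmark exists.
    ``n_inferior_20`` is inclusive of ``n_inferior_100``.
    """

    n_constructs: int
    n_non_inferior: int
    n_inconclusive: int
    n_inferior_20: int
    n_inferior_100: int


@dataclass(frozen=True, slots=True)
class StratumReport:
    """Benchmark and comparison table for one stratum at one timepoint."""

    stratum: Stratum
    t: float
    benchmark: object | None          # construct key, or None when unanalysable
    benchmark_estimate: KMEstimate | None
    comparisons: tuple[ComparisonResult, ...]
    summary: SummaryCounts
    figure_threshold: int

    @property
    def analysable(self) -> bool:
        return self.benchmark is not None


def summarise_counts(report: StratumReport, threshold: int) -> SummaryCounts:
    """Tally equivalence statuses over comparisons with at-risk >= threshold.

    The benchmark construct counts toward ``n_constructs`` (it is a
    construct in use meeting any threshold up to its own at-risk count)
    but never toward a status tally; inferior-by->=100% is counted within
    the inferior-by->=20% total.
    """
    eligible = [c for c in report.comparisons if c.n_at_risk >= threshold]
    n100 = sum(c.status is Status.INFERIOR_100 for c in eligible)
    n20 = n100 + sum(c.status is Status.INFERIOR_20 for c in eligible)
    n_ni = sum(c.status is Status.NON_INFERIOR for c in eligible)
    n_inc = sum(c.status is Status.INCONCLUSIVE for c in eligible)
    bench = 0
    if report.benchmark is not None and report.benchmark_estimate is not None:
        bench = int(report.benchmark_estimate.n_at_risk_at_t >= threshold)
    return SummaryCounts(
        n_constructs=len(eligible) + bench,
        n_non_inferior=n_ni,
        n_inconclusive=n_inc,
        n_inferior_20=n20,
        n_inferior_100=n100,
    )


def _construct_estimators(df: pd.DataFrame) -> dict[ConstructKey, KaplanMeierFailure]:
    fitted = {}
    for key_vals, grp in df.groupby(_CONSTRUCT_COLS, sort=True):
        key = ConstructKey(*key_vals)
        fitted[key] = KaplanMeierFailure().fit(grp)
    return fitted


def _report_for_cell(
    estimates: dict[ConstructKey, KMEstimate],
    stratum: Stratum,
    t: float,
    config: AnalysisConfig,
    benchmark_key: ConstructKey | None = None,
) -> StratumReport:
    """Assemble one cell's report; ``benchmark_key`` forces the reference
    (sensitivity analysis), otherwise it is selected contemporaneously."""
    if benchmark_key is None:
        try:
            benchmark_key = select_benchmark(estimates, config.benchmark_min_at_risk)
        except NoBenchmarkAvailable:
            logger.warning("no benchmark available for stratum (%s) at %gy", stratum.label, t)
            empty = SummaryCounts(0, 0, 0, 0, 0)
            return StratumReport(stratum, t, None, None, (), empty, config.figure_threshold)
    ref = estimates[benchmark_key]
    comparisons = []
    for key in sorted(estimates, key=str):
        if key == benchmark_key:
            continue
        est = estimates[key]
        if est.n_at_risk_at_t < config.table_threshold:
            continue
        comparisons.append(
            compare(est, ref, comparator_key=key, reference_key=benchmark_key,
                    margins=config.margins)
        )
    report = StratumReport(
        stratum, t, benchmark_key, ref, tuple(comparisons),
        SummaryCounts(0, 0, 0, 0, 0), config.figure_threshold,
    )
    return replace(report, summary=summarise_counts(report, config.figure_threshold))


def run_analysis(records: pd.DataFrame, config: AnalysisConfig | None = None) -> list[StratumReport]:
    """Contemporary-benchmark analysis over every stratum x timepoint.

    ``records`` must already have passed :func:`~kneebench.registry.apply_exclusions`.
    Returns one report per cell, in (stratum, timepoint) order; cells
    with no eligible benchmark come back with ``benchmark=None`` and an
    empty comparison list.
    """
    config = config or AnalysisConfig()
    reports = []
    for stratum in config.strata:
        sub = records.loc[stratum_mask(records, stratum, integer_ages=config.integer_ages)]
        fitted = _construct_estimators(sub)
        for t in config.timepoints:
            estimates = {k: km.failure_at(t) for k, km in fitted.items()}
            reports.append(_report_for_cell(estimates, stratum, t, config))
    return reports


def run_sensitivity(records: pd.DataFrame, config: AnalysisConfig | None = None) -> list[StratumReport]:
    """Historical-benchmark sensitivity analysis.

    The benchmark is selected once per stratum at
    ``config.sensitivity_benchmark_time`` (it must meet the at-risk floor
    there) and then serves as the reference at every earlier configured
    timepoint.  Strata with no benchmark at the anchor time are skipped
    with a log entry.
    """
    config = config or AnalysisConfig()
    if config.sensitivity_benchmark_time is None:
        raise ValueError("sensitivity_benchmark_time must be set to run the sensitivity analysis")
    anchor = float(config.sensitivity_benchmark_time)
    reports = []
    for stratum in config.strata:
        sub = records.loc[stratum_mask(records, stratum, integer_ages=config.integer_ages)]
        fitted = _construct_estimators(sub)
        anchor_estimates = {k: km.failure_at(anchor) for k, km in fitted.items()}
        try:
            bench = select_benchmark(anchor_estimates, config.benchmark_min_at_risk)
        except NoBenchmarkAvailable:
            logger.warning(
                "sensitivity: no benchmark at %gy for stratum (%s); stratum skipped",
                anchor, stratum.label,
            )
            continue
        for t in (tp for tp in config.timepoints if tp < anchor):
            estimates = {k: km.failure_at(t) for k, km in fitted.items()}
            reports.append(_report_for_cell(estimates, stratum, t, config, benchmark_key=bench))
    return reports


class StratifiedBenchmarkAnalysis(BaseEstimator):
    """Full registry benchmarking analysis as an sklearn-style estimator.

    Parameters mirror :class:`AnalysisConfig`; ``fit`` takes the included
    procedure table and populates ``reports_`` (and, when
    ``sensitivity_benchmark_time`` is set, ``sensitivity_reports_``).

    Attributes
    ----------
    reports_ : list of StratumReport
    sensitivity_reports_ : list of StratumReport
    """

    def __init__(
        self,
        timepoints: tuple[float, ...] = (3.0, 5.0, 7.0, 10.0),
        benchmark_min_at_risk: int = 1000,
        figure_threshold: int = 500,
        table_threshold: int = 250,
        margins: tuple[float, float] = (0.20, 1.00),
        strata: tuple[Stratum, ...] | None = None,
        sensitivity_benchmark_time: float | None = 10.0,
        integer_ages: bool = False,
        run_sensitivity: bool = False,
    ):
        self.timepoints = timepoints
        self.benchmark_min_at_risk = benchmark_min_at_risk
        self.figure_threshold = figure_threshold
        self.table_threshold = table_threshold
        self.margins = margins
        self.strata = strata
        self.sensitivity_benchmark_time = sensitivity_benchmark_time
        self.integer_ages = integer_ages
        self.run_sensitivity = run_sensitivity

    def _config(self) -> AnalysisConfig:
        return AnalysisConfig(
            timepoints=tuple(self.timepoints),
            benchmark_min_at_risk=self.benchmark_min_at_risk,
            figure_threshold=self.figure_threshold,
            table_threshold=self.table_threshold,
            margins=tuple(self.margins),
            strata=tuple(self.strata) if self.strata is not None else default_strata(),
            sensitivity_benchmark_time=self.sensitivity_benchmark_time,
            integer_ages=self.integer_ages,
        )

    def fit(self, X: pd.DataFrame, y=None):
        """Run the analysis on an included procedure table."""
        config = self._config()
        self.config_ = config
        self.reports_ = run_analysis(X, config)
        if self.run_sensitivity:
            self.sensitivity_reports_ = run_sensitivity(X, config)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Flatten fitted reports into one tidy comparison DataFrame."""
        if not hasattr(self, "reports_"):
            raise AttributeError("fit must be called before transform")
        return reports_to_frame(self.reports_)


def reports_to_frame(reports: list[StratumReport]) -> pd.DataFrame:
    """One row per comparison, percent-scaled, with stratum/time columns."""
    rows = []
    for rep in reports:
        for c in rep.comparisons:
            rows.append(
                {
                    "gender": rep.stratum.gender,
                    "age_band": rep.stratum.age_band,
                    "t": rep.t,
                    "construct": str(c.comparator),
                    "benchmark": str(c.reference),
                    "n_at_risk": c.n_at_risk,
                    "failure_pct": 100 * c.f_xi,
                    "benchmark_failure_pct": 100 * c.f_ref,
                    "difference_pct": 100 * c.diff,
                    "ci_low_pct": 100 * c.ci_low,
                    "ci_high_pct": 100 * c.ci_high,
                    "p_value": c.p_value,
                    "status": str(c.status),
                }
            )
    return pd.DataFrame(rows)
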