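"""Reading and writing the package's file formats.

Procedure CSV
    One row per primary procedure: ``procedure_id, brand, fixation,
    constraint, bearing, klass, gender, age_at_primary, time_years,
    event`` (plus optional ``valid_construct, patellofemoral, traceable``
    flags).  Instead of ``time_years`` a file may carry ``primary_date``
    and ``end_date`` (ISO dates); the reader converts them to years at
    day resolution.  Missing gender or age yields flagged records —
    dropping them is the exclusion filter's job, not the reader's.

Report CSV
    One file per stratum x timepoint, mirroring the layout of published
    benchmarking tables: reference row first, comparators sorted by
    label, percentages at 2 decimals, p-values at 3 with a "<0.001"
    floor.

Config files are flat YAML mirroring the analysis and scenario fields.
"""

from __future__ import annotations

import csv
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import AnalysisConfig, StratumReport, default_strata
from .registry import PROCEDURE_COLUMNS, Stratum
from .simulate import ConstructScenario, RegistryScenario
from .registry import ConstructKey

__all__ = [
    "SchemaError",
    "RowErrors",
    "read_procedures",
    "write_procedures",
    "write_report",
    "plot_report",
    "read_analysis_config",
    "write_analysis_config",
    "read_scenario",
    "write_scenario",
]

DAY = 1.0 / 365.25

_MANDATORY = ["procedure_id", "brand", "fixation", "constraint", "bearing",
              "klass", "gender", "age_at_primary", "event"]
_EVENTS = {"revision", "death", "administrative"}
_FLAGS = {"valid_construct": True, "patellofemoral": False, "traceable": True}


class SchemaError(ValueError):
    """The file header does not match the procedure schema."""


class RowErrors(ValueError):
    """One or more data rows failed to parse; ``errors`` lists them."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{len(errors)} malformed row(s): {lines}{more}")


def read_procedures(path) -> pd.DataFrame:
    """Read a procedure CSV into the canonical procedure table.

    Event labels are matched case-insensitively ("Revision" == "revision").
    Missing gender or age produce records flagged as missing rather than
    being dropped.  Malformed rows raise :class:`RowErrors` carrying
    1-based line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"procedure_id": str, "gender": str})
    cols = set(df.columns)
    has_time = "time_years" in cols
    has_dates = {"primary_date", "end_date"} <= cols
    for col in _MANDATORY:
        if col not in cols:
            raise SchemaError(f"missing mandatory column {col!r}")
    if not has_time and not has_dates:
        raise SchemaError("need either 'time_years' or 'primary_date'+'end_date' columns")

    errors: list[tuple[int, str]] = []

    event = df["event"].astype(str).str.strip().str.lower()
    bad = ~event.isin(_EVENTS)
    for idx in df.index[bad]:
        errors.append((int(idx) + 2, f"unparseable event value {df.at[idx, 'event']!r}"))
    df["event"] = event

    if not has_time:
        start = pd.to_datetime(df["primary_date"], errors="coerce")
        end = pd.to_datetime(df["end_date"], errors="coerce")
        for idx in df.index[start.isna() | end.isna()]:
            errors.append((int(idx) + 2, "unparseable primary_date/end_date"))
        days = (end - start).dt.days
        df["time_years"] = np.round(days) * DAY

    t = pd.to_numeric(df["time_years"], errors="coerce")
    for idx in df.index[t.isna() & df["time_years"].notna()] if has_time else []:
        errors.append((int(idx) + 2, f"unparseable time_years {df.at[idx, 'time_years']!r}"))
    neg = t < 0
    for idx in df.index[neg.fillna(False)]:
        errors.append((int(idx) + 2, f"negative time_years {t[idx]}"))
    df["time_years"] = t

    if errors:
        raise RowErrors(sorted(set(errors)))

    gender = df["gender"].fillna("missing").str.strip().str.lower()
    gender = gender.where(gender.isin(["male", "female"]), "missing")
    df["gender"] = gender
    df["age_at_primary"] = pd.to_numeric(df["age_at_primary"], errors="coerce")

    for col, default in _FLAGS.items():
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].map(
                lambda v: default if pd.isna(v) else str(v).strip().lower() in ("true", "1", "yes")
            )
    return df[PROCEDURE_COLUMNS]


def write_procedures(df: pd.DataFrame, path) -> None:
    """Write the procedure table; round-trips exactly at day resolution."""
    out = df.copy()
    out["time_years"] = (np.round(out["time_years"].astype(float) / DAY)).astype(int) * DAY
    out["time_years"] = out["time_years"].map(lambda v: f"{v:.10f}")
    out.to_csv(path, index=False)


def _fmt_pct(x: float) -> str:
    return f"{100.0 * x:.2f}"


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


REPORT_COLUMNS = [
    "construct_label", "n_at_risk", "cumulative_failure_pct", "difference_pct",
    "ci_low_pct", "ci_high_pct", "equivalence_status", "p_value",
]


def write_report(report: StratumReport, path, *, plot: bool = False) -> None:
    """Emit one stratum x timepoint report CSV (reference row first,
    comparators sorted by label); optionally a companion difference plot
    next to it (same stem, ``.svg``)."""
    rows = []
    if report.benchmark is not None:
        rows.append({
            "construct_label": str(report.benchmark),
            "n_at_risk": report.benchmark_estimate.n_at_risk_at_t,
            "cumulative_failure_pct": _fmt_pct(report.benchmark_estimate.failure),
            "difference_pct": "", "ci_low_pct": "", "ci_high_pct": "",
            "equivalence_status": "(Reference)", "p_value": "",
        })
    for c in sorted(report.comparisons, key=lambda c: str(c.comparator)):
        rows.append({
            "construct_label": str(c.comparator),
            "n_at_risk": c.n_at_risk,
            "cumulative_failure_pct": _fmt_pct(c.f_xi),
            "difference_pct": _fmt_pct(c.diff),
            "ci_low_pct": _fmt_pct(c.ci_low),
            "ci_high_pct": _fmt_pct(c.ci_high),
            "equivalence_status": c.status.printed,
            "p_value": _fmt_p(c.p_value),
        })
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    if plot:
        plot_report(report, path.with_suffix(".svg"))


def plot_report(report: StratumReport, path) -> None:
    """Difference plot: per construct, the failure difference versus the
    benchmark with 95% CI whiskers and vertical margin lines at delta_20
    and delta_100."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = [c for c in report.comparisons if c.n_at_risk >= report.figure_threshold]
    comps.sort(key=lambda c: c.diff)
    if not comps:
        fig, ax = plt.subplots(figsize=(6, 2))
        ax.text(0.5, 0.5, "no comparators at figure threshold", ha="center", va="center")
        ax.set_axis_off()
        fig.savefig(path)
        plt.close(fig)
        return
    labels = [str(c.comparator) for c in comps]
    y = np.arange(len(comps))
    diffs = np.array([100 * c.diff for c in comps])
    lo = np.array([100 * (c.diff - c.ci_low) for c in comps])
    hi = np.array([100 * (c.ci_high - c.diff) for c in comps])
    fig, ax = plt.subplots(figsize=(8, max(3, 0.22 * len(comps) + 1.5)))
    ax.errorbar(diffs, y, xerr=[lo, hi], fmt="o", ms=3, lw=1, color="k", capsize=2)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.axvline(100 * comps[0].delta_20, color="tab:orange", ls="--", lw=1, label="20% margin")
    ax.axvline(100 * comps[0].delta_100, color="tab:red", ls="--", lw=1, label="100% margin")
    ax.set_yticks(y, labels, fontsize=6)
    ax.set_xlabel("difference in cumulative failure vs benchmark (%)")
    ax.set_title(f"{report.stratum.label} at {report.t:g} years", fontsize=9)
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# --- configuration files -------------------------------------------------

def write_analysis_config(config: AnalysisConfig, path) -> None:
    data = {
        "timepoints": list(config.timepoints),
        "benchmark_min_at_risk": config.benchmark_min_at_risk,
        "figure_threshold": config.figure_threshold,
        "table_threshold": config.table_threshold,
        "margins": list(config.margins),
        "strata": [{"gender": s.gender, "age_band": s.age_band} for s in config.strata],
        "sensitivity_benchmark_time": config.sensitivity_benchmark_time,
        "integer_ages": config.integer_ages,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_analysis_config(path) -> AnalysisConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    strata = data.pop("strata", None)
    if strata is not None:
        data["strata"] = tuple(Stratum(**s) for s in strata)
    else:
        data["strata"] = default_strata()
    for key in ("timepoints", "margins"):
        if key in data:
            data[key] = tuple(data[key])
    return AnalysisConfig(**data)


def write_scenario(scenario: RegistryScenario, path) -> None:
    data = {
        "accrual_window": list(scenario.accrual_window),
        "admin_censor_date": scenario.admin_censor_date,
        "death_hazard_base": scenario.death_hazard_base,
        "death_hazard_age_slope": scenario.death_hazard_age_slope,
        "gender_mix": scenario.gender_mix,
        "age_distribution": list(scenario.age_distribution),
        "seed": scenario.seed,
        "constructs": [
            {
                "brand": sc.construct.brand,
                "fixation": str(sc.construct.fixation),
                "constraint": str(sc.construct.constraint),
                "bearing": str(sc.construct.bearing),
                "klass": str(sc.construct.klass),
                "n_procedures": sc.n_procedures,
                "revision_hazard": [list(map(float, seg)) for seg in sc.revision_hazard],
                "market_share_by_year": (
                    list(sc.market_share_by_year) if sc.market_share_by_year else None
                ),
            }
            for sc in scenario.scenarios
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_scenario(path) -> RegistryScenario:
    data = yaml.safe_load(Path(path).read_text())
    constructs = []
    for c in data.pop("constructs"):
        key = ConstructKey(c["brand"], c["fixation"], c["constraint"], c["bearing"], c["klass"])
        share = c.get("market_share_by_year")
        constructs.append(
            ConstructScenario(
                key, int(c["n_procedures"]),
                tuple(tuple(seg) for seg in c["revision_hazard"]),
                tuple(share) if share else None,
            )
        )
    for key in ("accrual_window", "age_distribution"):
        if key in data:
            data[key] = tuple(data[key])
    return RegistryScenario(scenarios=tuple(constructs), **data)
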