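"""Published benchmark tables as machine-readable fixtures.

Two gender-specific 5-year comparison tables ship with the package
(``men_5y``, ``women_5y``): per construct, the number at risk, the
cumulative net failure, the difference in failure versus the reference
construct with its 95% CI, the printed equivalence status and p-value.
They serve as ground truth for the benchmark-selection rule and for the
CI-versus-margin classifier, and as worked input for the report writer.

All percentages keep the published 2-decimal rounding; re-derived
differences are therefore compared with a +/-0.01 absolute tolerance,
while equivalence statuses must match exactly.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .benchmark import Status, Z_95, ComparisonResult, classify, select_benchmark
from .pipeline import StratumReport, SummaryCounts, summarise_counts
from .registry import Stratum
from .survival import KMEstimate

__all__ = [
    "TABLE_NAMES",
    "load_table",
    "table_estimates",
    "reference_row",
    "table_report",
    "verify_table",
]

TABLE_NAMES = ("men_5y", "women_5y")
_GENDER = {"men_5y": "male", "women_5y": "female"}
_T = 5.0

_STATUS_FROM_PRINTED = {
    "Non-inferior": Status.NON_INFERIOR,
    "Non-inferiority not shown": Status.INCONCLUSIVE,
    "Inferior by >=20%": Status.INFERIOR_20,
    "Inferior by >=100%": Status.INFERIOR_100,
}


def load_table(name: str) -> pd.DataFrame:
    """Load one published comparison table fixture by name."""
    if name not in TABLE_NAMES:
        raise ValueError(f"unknown table {name!r}; available: {TABLE_NAMES}")
    with resources.files("kneebench.data").joinpath(f"{name}.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def reference_row(df: pd.DataFrame) -> pd.Series:
    ref = df[df["status"] == "Reference"]
    if len(ref) != 1:
        raise ValueError("table must contain exactly one reference row")
    return ref.iloc[0]


def table_estimates(df: pd.DataFrame) -> dict[str, KMEstimate]:
    """Per-construct failure estimates keyed by printed label.

    Greenwood SEs are not printed per construct, so ``gse`` is set to
    NaN; benchmark selection needs only the failure and at-risk count.
    """
    out: dict[str, KMEstimate] = {}
    for row in df.itertuples(index=False):
        out[row.label] = KMEstimate(
            t=_T,
            failure=row.failure_pct / 100.0,
            gse=float("nan"),
            n_at_risk_at_t=int(row.n_at_risk),
            n_events_by_t=0,
        )
    return out


def _row_comparison(row, ref_label: str, f_ref: float,
                    margins: tuple[float, float]) -> ComparisonResult:
    """Rebuild one comparison from printed values (proportion scale)."""
    diff = row.diff_pct / 100.0
    lo, hi = row.ci_low_pct / 100.0, row.ci_high_pct / 100.0
    se = (hi - lo) / (2.0 * Z_95)
    d20, d100 = margins[0] * f_ref, margins[1] * f_ref
    status = classify(lo, hi, d20, d100)
    from scipy.stats import norm

    z = diff / se if se > 0 else 0.0
    return ComparisonResult(
        comparator=row.label,
        reference=ref_label,
        t=_T,
        f_xi=row.failure_pct / 100.0,
        f_ref=f_ref,
        diff=diff,
        se_diff=se,
        ci_low=lo,
        ci_high=hi,
        delta_20=d20,
        delta_100=d100,
        z_noninf=(diff - d20) / se if se > 0 else 0.0,
        p_value=float(norm.sf(abs(z))),
        p_noninf=float(norm.cdf((diff - d20) / se)) if se > 0 else 0.5,
        status=status,
        n_at_risk=int(row.n_at_risk),
    )


def table_report(name: str, margins: tuple[float, float] = (0.20, 1.00),
                 figure_threshold: int = 500) -> StratumReport:
    """Reconstruct the stratum report for one published table.

    The classifier is re-applied to every printed CI against margins
    derived from the printed reference failure; printed statuses are not
    copied into the result.
    """
    df = load_table(name)
    ref = reference_row(df)
    f_ref = ref.failure_pct / 100.0
    comparisons = tuple(
        _row_comparison(row, ref.label, f_ref, margins)
        for row in df.itertuples(index=False)
        if row.status != "Reference"
    )
    stratum = Stratum(gender=_GENDER[name])
    ref_est = KMEstimate(t=_T, failure=f_ref, gse=float("nan"),
                         n_at_risk_at_t=int(ref.n_at_risk), n_events_by_t=0)
    report = StratumReport(
        stratum, _T, ref.label, ref_est, comparisons,
        SummaryCounts(0, 0, 0, 0, 0), figure_threshold,
    )
    from dataclasses import replace

    return replace(report, summary=summarise_counts(report, figure_threshold))


def verify_table(name: str, diff_tol: float = 0.01) -> pd.DataFrame:
    """Re-derive each printed row and flag any disagreement.

    Checks three things per comparator row: the benchmark-selection rule
    picks the printed reference; the difference recomputed from the two
    printed failures is within ``diff_tol`` (percentage points, to absorb
    print rounding) of the printed difference; and the CI-versus-margin
    classifier reproduces the printed equivalence status exactly.
    """
    df = load_table(name)
    ref = reference_row(df)
    est = table_estimates(df)
    chosen = select_benchmark(est, min_at_risk=1000)
    rows = []
    for row in df.itertuples(index=False):
        if row.status == "Reference":
            continue
        rederived_diff = row.failure_pct - ref.failure_pct
        d20 = 0.20 * ref.failure_pct
        d100 = 1.00 * ref.failure_pct
        status = classify(row.ci_low_pct, row.ci_high_pct, d20, d100)
        printed = _STATUS_FROM_PRINTED[row.status]
        rows.append(
            {
                "label": row.label,
                "printed_diff": row.diff_pct,
                "rederived_diff": rederived_diff,
                "diff_ok": bool(abs(rederived_diff - row.diff_pct) <= diff_tol + 1e-12),
                "printed_status": str(printed),
                "rederived_status": str(status),
                "status_ok": status is printed,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["benchmark_ok"] = chosen == ref.label
    out.attrs["benchmark"] = chosen
    out.attrs["reference_failure_pct"] = float(ref.failure_pct)
    return out
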