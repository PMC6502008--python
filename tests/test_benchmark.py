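"""Benchmark selection, margin comparison and CI-rule classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneebench.benchmark import (
    DegenerateComparison,
    Margin,
    NoBenchmarkAvailable,
    Status,
    Z_95,
    classify,
    compare,
    select_benchmark,
)
from kneebench.survival import KMEstimate
from kneebench.tables import load_table, reference_row, table_estimates


def est(failure, gse=0.0, n=5000, t=5.0):
    return KMEstimate(t=t, failure=failure, gse=gse, n_at_risk_at_t=n, n_events_by_t=0)


class TestSelectBenchmark:
    def test_mens_table_excludes_low_volume_lowest_failure(self):
        # the 1.21% construct with only 856 at risk is ineligible; the
        # 1.76% construct with 8639 at risk wins
        df = load_table("men_5y")
        chosen = select_benchmark(table_estimates(df), min_at_risk=1000)
        assert chosen == "NexGen cemented, unconstrained fixed"
        assert reference_row(df).failure_pct == 1.76

    def test_womens_table_benchmark(self):
        df = load_table("women_5y")
        chosen = select_benchmark(table_estimates(df), min_at_risk=1000)
        assert chosen == "MRK cemented, unconstrained fixed"
        assert reference_row(df).failure_pct == 1.35

    def test_single_eligible_construct(self):
        assert select_benchmark({"A": est(0.05, n=1500)}) == "A"

    def test_no_eligible_raises(self):
        with pytest.raises(NoBenchmarkAvailable):
            select_benchmark({"A": est(0.01, n=999)})

    def test_tie_broken_by_larger_at_risk_then_label(self):
        estimates = {"B": est(0.02, n=2000), "A": est(0.02, n=2000), "C": est(0.02, n=9000)}
        assert select_benchmark(estimates) == "C"
        del estimates["C"]
        assert select_benchmark(estimates) == "A"

    def test_benchmark_optimality_property(self, rng):
        for _ in range(50):
            estimates = {
                f"K{i}": est(rng.uniform(0, 0.2), n=int(rng.integers(100, 5000)))
                for i in range(12)
            }
            try:
                best = select_benchmark(estimates)
            except NoBenchmarkAvailable:
                assert all(e.n_at_risk_at_t < 1000 for e in estimates.values())
                continue
            eligible = [e for e in estimates.values() if e.n_at_risk_at_t >= 1000]
            assert estimates[best].failure <= min(e.failure for e in eligible)


class TestClassify:
    # margins on the men's-table reference: delta20 = 0.352, delta100 = 1.76 (%)
    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((-0.16, 0.30), Status.NON_INFERIOR),     # upper CI below the 20% margin
            ((1.89, 5.13), Status.INFERIOR_100),      # lower CI above the 100% margin
            ((1.75, 3.44), Status.INFERIOR_20),       # 1.75 < 1.76: not past 100%
            ((0.29, 3.20), Status.INCONCLUSIVE),      # straddles the 20% margin
            ((0.352, 0.40), Status.INCONCLUSIVE),     # lower bound ON the margin
            ((0.30, 0.352), Status.NON_INFERIOR),     # upper bound ON the margin
        ],
    )
    def test_ci_rule(self, ci, expected):
        assert classify(ci[0], ci[1], 0.352, 1.76) is expected

    def test_strongest_status_reported(self):
        # lower CI above delta100 implies the 20% condition too
        assert classify(2.0, 3.0, 0.352, 1.76) is Status.INFERIOR_100

    def test_monotone_in_margin(self, rng):
        # enlarging the margins never moves the status toward inferior
        order = [Status.INFERIOR_100, Status.INFERIOR_20, Status.INCONCLUSIVE,
                 Status.NON_INFERIOR]
        for _ in range(200):
            lo = rng.uniform(-2, 4)
            hi = lo + rng.uniform(0, 4)
            d20a, d20b = sorted(rng.uniform(0, 2, size=2))
            scale = rng.uniform(1, 5)
            a = classify(lo, hi, d20a, scale * d20a)
            b = classify(lo, hi, d20b, scale * d20b)
            assert order.index(b) >= order.index(a)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify(1.0, 0.5, 0.2, 1.0)
        with pytest.raises(ValueError):
            classify(0.0, 1.0, 1.0, 0.2)


class TestCompare:
    def test_paper_differences(self):
        # printed failures whose difference is exact at 2 decimals
        r = compare(est(0.0228, gse=0.001), est(0.0176, gse=0.001))
        assert r.diff * 100 == pytest.approx(0.52)
        r = compare(est(0.0572, gse=0.001), est(0.0176, gse=0.001))
        assert r.diff * 100 == pytest.approx(3.96)

    def test_pooled_se_and_symmetric_ci(self):
        c, ref = est(0.05, gse=0.004), est(0.02, gse=0.003)
        r = compare(c, ref)
        assert r.se_diff == pytest.approx(math.hypot(0.004, 0.003))
        assert r.ci_high - r.diff == pytest.approx(r.diff - r.ci_low)
        assert r.ci_high - r.ci_low == pytest.approx(2 * Z_95 * r.se_diff)

    def test_p_value_convention_matches_printed_tables(self):
        # one-sided upper tail of |diff|/se: diff -0.55%, CI (-1.26, 0.16)
        se = ((0.16 - -1.26) / 100) / (2 * Z_95)
        gse = se / math.sqrt(2)
        r = compare(est(0.0121, gse=gse), est(0.0176, gse=gse))
        assert r.p_value == pytest.approx(0.064, abs=5e-4)
        # zero difference -> p = 0.5 (FS row convention: printed 0.497)
        r0 = compare(est(0.0176, gse=0.003), est(0.0176, gse=0.003))
        assert r0.p_value == pytest.approx(0.5)

    def test_self_comparison(self):
        e = est(0.03, gse=0.002)
        r = compare(e, e)
        assert r.diff == 0.0
        assert r.status in (Status.NON_INFERIOR, Status.INCONCLUSIVE)

    def test_antisymmetry(self):
        a, b = est(0.05, gse=0.004), est(0.02, gse=0.003)
        fwd, rev = compare(a, b), compare(b, a)
        assert fwd.diff == pytest.approx(-rev.diff)
        assert fwd.ci_low == pytest.approx(-rev.ci_high)
        assert fwd.ci_high == pytest.approx(-rev.ci_low)

    def test_z_sign_switch(self):
        a, b = est(0.05, gse=0.004), est(0.02, gse=0.003)
        minus = compare(a, b).z_noninf
        plus = compare(a, b, printed_sign=True).z_noninf
        d20 = 0.2 * 0.02
        assert plus - minus == pytest.approx(2 * d20 / math.hypot(0.004, 0.003))

    def test_degenerate_comparison(self):
        with pytest.raises(DegenerateComparison):
            compare(est(0.05, gse=0.0), est(0.02, gse=0.0))

    def test_zero_reference_flags_margin_undefined(self):
        r = compare(est(0.01, gse=0.002), est(0.0, gse=0.001))
        assert r.margin_undefined
        assert r.delta_20 == 0.0 and r.delta_100 == 0.0

    def test_mismatched_times_rejected(self):
        with pytest.raises(ValueError):
            compare(est(0.05, t=5.0), est(0.02, t=3.0))


class TestMargin:
    def test_absolute_scaling(self):
        assert Margin(0.20).absolute_at(0.0176) == pytest.approx(0.00352)
        assert Margin(1.00).absolute_at(0.0176) == pytest.approx(0.0176)
        assert Margin(1.00).absolute_at(0.05) > Margin(0.20).absolute_at(0.05)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            Margin(0.0)


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    f_xi=st.floats(0.0, 0.3),
    f_ref=st.floats(1e-4, 0.2),
    g1=st.floats(1e-4, 0.02),
    g2=st.floats(1e-4, 0.02),
)
def test_status_consistency_property(f_xi, f_ref, g1, g2):
    """The reported status is the strongest applicable one, and the CI
    always brackets the point difference."""
    r = compare(est(f_xi, gse=g1), est(f_ref, gse=g2))
    assert r.ci_low <= r.diff <= r.ci_high
    if r.status is Status.INFERIOR_100:
        assert r.ci_low > r.delta_20  # the 20% condition holds as well
    if r.status is Status.NON_INFERIOR:
        assert r.ci_high <= r.delta_20
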