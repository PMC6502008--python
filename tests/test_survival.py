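"""Product-limit engine: hand-computed risk sets, Greenwood behaviour,
brute-force and lifelines cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneebench.survival import (
    DAY,
    KaplanMeierFailure,
    at_risk,
    build_risk_table,
    km_failure,
)


def brute_failure_gse(times, events, t):
    """Direct product-limit recomputation by exhaustive enumeration of risk
    sets at every distinct event time (independent of the implementation)."""
    times = list(times)
    events = list(events)
    surv, gsum = 1.0, 0.0
    for s in sorted({x for x, e in zip(times, events) if e}):
        if s > t:
            break
        n = sum(1 for x in times if x >= s)  # censored at s still at risk
        d = sum(1 for x, e in zip(times, events) if e and x == s)
        surv *= 1 - d / n
        if n > d:
            gsum += d / (n * (n - d))
    return 1.0 - surv, surv * np.sqrt(gsum)


class TestRiskTable:
    def test_hand_constructed_risk_sets(self):
        # revision at 1, death at 2, revision at 3 among n=3
        table = build_risk_table([1.0, 2.0, 3.0], [True, False, True])
        assert table.event_times.tolist() == [1.0, 3.0]
        assert table.d.tolist() == [1, 1]
        assert table.n.tolist() == [3, 1]

    def test_no_revisions_gives_empty_table(self):
        table = build_risk_table([5.0] * 4, [False] * 4)
        assert len(table) == 0
        assert table.n_total == 4

    def test_tied_revision_and_death_event_first(self):
        # tie at t=2: the death censored at 2 still counts in the risk set
        table = build_risk_table([2.0, 2.0, 3.0, 4.0], [True, False, False, False])
        assert table.event_times.tolist() == [2.0]
        assert table.d.tolist() == [1]
        assert table.n.tolist() == [4]

    def test_zero_time_revision_shifted_to_one_day(self):
        table = build_risk_table([0.0, 1.0], [True, False])
        assert table.event_times[0] == pytest.approx(DAY)

    def test_empty_input(self):
        table = build_risk_table([], [])
        assert len(table) == 0 and table.n_total == 0


class TestKMFailure:
    def test_hand_product_limit(self):
        # risk sets {t=1: d=1, n=4} and {t=3: d=1, n=2}
        table = build_risk_table([1.0, 2.0, 3.0, 5.0], [True, False, True, False])
        est = km_failure(table, 3.0)
        assert est.failure == pytest.approx(1 - (3 / 4) * (1 / 2))

    def test_no_censoring_reduces_to_binomial(self):
        # 10 revisions among 100 by t: failure 0.10, gse = binomial SE exactly
        times = np.concatenate([np.linspace(0.5, 4.5, 10), np.full(90, 9.0)])
        events = np.concatenate([np.ones(10, bool), np.zeros(90, bool)])
        est = km_failure(build_risk_table(times, events), 5.0)
        assert est.failure == pytest.approx(0.10, abs=1e-15)
        assert est.gse == pytest.approx(np.sqrt(0.1 * 0.9 / 100), abs=1e-15)

    def test_empty_table_zero_failure(self):
        est = km_failure(build_risk_table([], []), 5.0)
        assert est.failure == 0.0 and est.gse == 0.0

    def test_gse_zero_before_first_event(self):
        table = build_risk_table([4.0, 6.0], [True, False])
        est = km_failure(table, 2.0)
        assert est.failure == 0.0 and est.gse == 0.0

    def test_extrapolation_flagged_and_carried_forward(self):
        table = build_risk_table([1.0, 2.0], [True, False])
        est = km_failure(table, 10.0)
        assert est.extrapolated
        assert est.failure == pytest.approx(0.5)
        assert est.n_at_risk_at_t == 0

    def test_failure_reaches_one_and_gse_truncates(self):
        # everyone revised: S hits 0; the Greenwood sum must stop at the
        # last factor with n > d instead of dividing by zero
        table = build_risk_table([1.0, 2.0], [True, True])
        est = km_failure(table, 3.0)
        assert est.failure == 1.0
        assert np.isfinite(est.gse)

    def test_failure_monotone_in_t(self, rng):
        times = rng.exponential(5, size=200)
        events = rng.uniform(size=200) < 0.6
        table = build_risk_table(times, events)
        vals = [km_failure(table, t).failure for t in np.linspace(0.1, 12, 40)]
        assert np.all(np.diff(vals) >= -1e-15)

    def test_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            km_failure(build_risk_table([1.0], [True]), 0.0)


class TestAtRisk:
    def test_boundary_included(self):
        assert at_risk([2.9, 3.0, 3.1], 3.0) == 2

    def test_t_zero_full_cohort(self):
        assert at_risk([1.0, 2.0, 3.0], 0.0) == 3

    def test_all_followed_past_t(self):
        assert at_risk([9.0, 8.0, 7.5], 5.0) == 3


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.data())
def test_brute_force_oracle_small_datasets(data):
    """On random datasets with n <= 12 the engine must match a direct
    risk-set enumeration at every distinct time, to machine precision."""
    n = data.draw(st.integers(1, 12))
    # day-grid times force ties between events and censorings
    times = data.draw(st.lists(st.integers(1, 40), min_size=n, max_size=n))
    events = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
    times = [k * 0.25 for k in times]
    table = build_risk_table(times, events)
    for t in sorted(set(times)) + [max(times) + 1.0]:
        t_eval = min(t, max(times))
        exp_f, exp_gse = brute_failure_gse(times, events, t_eval)
        est = km_failure(table, t)
        assert est.failure == pytest.approx(exp_f, abs=1e-12)
        assert est.gse == pytest.approx(exp_gse, abs=1e-12)
        if t <= max(times):
            assert est.n_at_risk_at_t == sum(1 for x in times if x >= t)


def test_matches_lifelines_on_censored_data(rng):
    """Independent cross-check against lifelines' Kaplan-Meier fitter."""
    lifelines = pytest.importorskip("lifelines")
    times = np.round(rng.exponential(6, size=500) * 365.25) / 365.25
    times = np.maximum(times, DAY)
    events = rng.uniform(size=500) < 0.5
    kmf = lifelines.KaplanMeierFitter().fit(times, events)
    km = KaplanMeierFailure().fit(times, events)
    for t in [1.0, 3.0, 5.0, 8.0]:
        mine = km.failure_at(t).failure
        theirs = 1.0 - float(kmf.survival_function_at_times(t).iloc[0])
        assert mine == pytest.approx(theirs, abs=1e-10)


class TestEstimator:
    def test_fit_from_dataframe_event_strings(self):
        from conftest import make_procedures

        df = make_procedures([1.0, 2.0, 3.0], ["revision", "death", "revision"])
        km = KaplanMeierFailure().fit(df)
        # risk sets: t=1 (n=3,d=1), t=3 (n=1,d=1) -> F = 1 - (2/3)(0) = 1
        assert km.failure_at(3.0).failure == pytest.approx(1.0)
        assert km.failure_at(2.5).failure == pytest.approx(1 / 3)

    def test_sklearn_clone_and_params(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.base import clone

        km = KaplanMeierFailure(zero_shift=0.01)
        km2 = clone(km)
        assert km2.get_params()["zero_shift"] == 0.01

    def test_predict_curve(self):
        km = KaplanMeierFailure().fit([1.0, 2.0, 4.0], [True, True, False])
        curve = km.predict([0.5, 1.5, 3.0])
        assert curve.tolist() == pytest.approx([0.0, 1 / 3, 1 / 3 + (2 / 3) * 0.5])
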