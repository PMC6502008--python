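"""Synthetic knee-replacement registry generator.

Emulates the statistical structure a national arthroplasty registry
extract presents to the analysis: many constructs with heterogeneous
revision hazards, uniform accrual over a calendar window, mortality
censoring whose pressure rises with age, and a fixed administrative
censoring date.  Revision times are piecewise-exponential per construct;
death times are exponential with a log-linear age effect — enough to
create realistic age-dependent censoring without a full life table.

Times are stored at day resolution (a 1/365.25-year grid), so tied event
times — which real registry data contain — occur and must be handled by
the product-limit engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registry import PROCEDURE_COLUMNS, ConstructKey

__all__ = [
    "ConstructScenario",
    "RegistryScenario",
    "ScenarioError",
    "simulate_registry",
    "scenario_like_paper",
]

DAY = 1.0 / 365.25
_REFERENCE_AGE = 70.0


class ScenarioError(ValueError):
    """A scenario field failed validation; the message names the field."""


@dataclass(frozen=True, slots=True)
class ConstructScenario:
    """Ground truth for one construct.

    ``revision_hazard`` is piecewise-constant: a list of
    ``(interval_end_years, rate_per_year)`` pairs with intervals
    contiguous from 0; the last interval must reach the maximum
    follow-up horizon of the registry scenario.
    """

    construct: ConstructKey
    n_procedures: int
    revision_hazard: tuple[tuple[float, float], ...]
    market_share_by_year: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "revision_hazard", tuple(map(tuple, self.revision_hazard)))
        if self.n_procedures < 0:
            raise ScenarioError("n_procedures: must be non-negative")
        prev = 0.0
        for end, rate in self.revision_hazard:
            if end <= prev:
                raise ScenarioError("revision_hazard: interval ends must increase from 0")
            if rate < 0:
                raise ScenarioError("revision_hazard: rates must be >= 0")
            prev = end
        if not self.revision_hazard:
            raise ScenarioError("revision_hazard: at least one interval required")
        if self.market_share_by_year is not None:
            ws = np.asarray(self.market_share_by_year, dtype=float)
            if np.any(ws < 0) or ws.sum() <= 0:
                raise ScenarioError("market_share_by_year: weights must be non-negative, not all zero")

    @property
    def horizon(self) -> float:
        return self.revision_hazard[-1][0]

    def true_failure(self, t: float) -> float:
        """Closed-form revision-time CDF at t (no competing risks)."""
        h, prev = 0.0, 0.0
        for end, rate in self.revision_hazard:
            h += rate * max(0.0, min(t, end) - prev)
            prev = end
            if t <= end:
                break
        return 1.0 - np.exp(-h)


@dataclass(frozen=True, slots=True)
class RegistryScenario:
    """Full generator configuration for one synthetic registry extract.

    Calendar positions are decimal years (2003.25 is 1 April 2003); the
    administrative censoring date must come after accrual starts.  Ages
    at primary are truncated-normal; the death hazard at age ``a`` is
    ``death_hazard_base * exp(death_hazard_age_slope * (a - 70))``.
    """

    scenarios: tuple[ConstructScenario, ...]
    accrual_window: tuple[float, float] = (2003.25, 2017.0)
    admin_censor_date: float = 2017.0
    death_hazard_base: float = 0.02
    death_hazard_age_slope: float = 0.09
    gender_mix: float = 0.43
    age_distribution: tuple[float, float, float, float] = (70.0, 9.0, 20.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        start, end = self.accrual_window
        if not start < end:
            raise ScenarioError("accrual_window: start must precede end")
        if not start < self.admin_censor_date:
            raise ScenarioError("admin_censor_date: must come after accrual starts")
        if not 0.0 <= self.gender_mix <= 1.0:
            raise ScenarioError("gender_mix: proportion must lie in [0, 1]")
        if self.death_hazard_base < 0:
            raise ScenarioError("death_hazard_base: must be >= 0")
        mean, sd, lo, hi = self.age_distribution
        if sd < 0 or lo >= hi:
            raise ScenarioError("age_distribution: need sd >= 0 and lo < hi")
        horizon = self.admin_censor_date - start
        for sc in self.scenarios:
            if sc.horizon < horizon - 1e-9:
                raise ScenarioError(
                    f"revision_hazard: construct {sc.construct.brand!r} hazard ends at "
                    f"{sc.horizon}y, before the maximum follow-up horizon {horizon:.2f}y"
                )

    @property
    def max_follow_up(self) -> float:
        return self.admin_censor_date - self.accrual_window[0]


def _sample_piecewise_exponential(rng, hazard, size: int) -> np.ndarray:
    """Inverse-CDF draws from a piecewise-constant-hazard distribution.

    Draws with total cumulative hazard below an Exp(1) deviate never fail
    within the hazard's support and come back as +inf.
    """
    ends = np.array([e for e, _ in hazard])
    rates = np.array([r for _, r in hazard])
    starts = np.concatenate([[0.0], ends[:-1]])
    seg = rates * (ends - starts)
    cum = np.concatenate([[0.0], np.cumsum(seg)])  # H at interval starts/ends
    u = rng.exponential(size=size)
    t = np.full(size, np.inf)
    idx = np.searchsorted(cum[1:], u, side="left")  # first interval where H >= u
    inside = idx < len(rates)
    i = idx[inside]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_in = starts[i] + (u[inside] - cum[i]) / rates[i]
    t[inside] = t_in
    return t


def simulate_registry(scenario: RegistryScenario, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic registry extract as a procedure table.

    For each procedure the accrual date is uniform in the window (or per
    the construct's yearly market share), a latent revision time comes
    from the construct's piecewise-exponential hazard, a latent death
    time from the age-dependent exponential, and the observed follow-up
    is the minimum of revision, death and the administrative horizon.
    Ties after rounding to the day grid resolve revision > death >
    administrative.  Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    start, end = scenario.accrual_window
    admin = scenario.admin_censor_date
    mean, sd, lo, hi = scenario.age_distribution

    frames = []
    offset = 0
    for sc in scenario.scenarios:
        n = sc.n_procedures
        if n == 0:
            continue
        if sc.market_share_by_year is not None:
            years = np.arange(int(np.floor(start)), int(np.floor(start)) + len(sc.market_share_by_year))
            w = np.asarray(sc.market_share_by_year, dtype=float)
            yr = rng.choice(years, size=n, p=w / w.sum())
            accrual = np.clip(yr + rng.uniform(0.0, 1.0, size=n), start, end)
        else:
            accrual = rng.uniform(start, end, size=n)

        age = rng.normal(mean, sd, size=n)
        for _ in range(20):  # resample out-of-range draws (truncated normal)
            bad = (age < lo) | (age > hi)
            if not bad.any():
                break
            age[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        age = np.clip(age, lo, hi)
        male = rng.uniform(size=n) < scenario.gender_mix

        t_rev = _sample_piecewise_exponential(rng, sc.revision_hazard, n)
        death_rate = scenario.death_hazard_base * np.exp(
            scenario.death_hazard_age_slope * (age - _REFERENCE_AGE)
        )
        with np.errstate(divide="ignore"):
            t_death = np.where(
                death_rate > 0, rng.exponential(1.0, size=n) / np.maximum(death_rate, 1e-300), np.inf
            )
        t_admin = admin - accrual

        # day grid; admin horizon rounded the same way so ties are honest
        grid = lambda x: np.round(np.asarray(x) / DAY) * DAY
        t_rev, t_death, t_admin = grid(t_rev), grid(t_death), grid(t_admin)

        obs = np.minimum(np.minimum(t_rev, t_death), t_admin)
        event = np.where(
            t_rev <= obs, "revision", np.where(t_death <= obs, "death", "administrative")
        )

        df = pd.DataFrame(
            {
                "procedure_id": [f"P{offset + j:07d}" for j in range(n)],
                "brand": sc.construct.brand,
                "fixation": str(sc.construct.fixation),
                "constraint": str(sc.construct.constraint),
                "bearing": str(sc.construct.bearing),
                "klass": str(sc.construct.klass),
                "gender": np.where(male, "male", "female"),
                "age_at_primary": np.round(age, 1),
                "time_years": obs,
                "event": event,
                "valid_construct": True,
                "patellofemoral": False,
                "traceable": True,
            }
        )
        frames.append(df)
        offset += n

    if not frames:
        return pd.DataFrame(columns=PROCEDURE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[PROCEDURE_COLUMNS]


def _const_hazard_for_failure(f_at_5: float, horizon: float) -> tuple[tuple[float, float], ...]:
    """Constant hazard whose 5-year failure equals ``f_at_5``."""
    lam = -np.log(1.0 - f_at_5) / 5.0
    return ((horizon, float(lam)),)


# (brand, fixation, constraint, bearing, true 5-year failure, n)
_TKR_MENU = [
    ("Atlas", "cemented", "unconstrained", "fixed", 0.012, 32000),  # benchmark-like
    ("Atlas", "cemented", "posterior_stabilised", "fixed", 0.022, 6000),
    ("Atlas", "uncemented", "unconstrained", "fixed", 0.024, 2500),
    ("Borealis", "cemented", "unconstrained", "fixed", 0.016, 9000),
    ("Borealis", "cemented", "unconstrained", "mobile", 0.026, 2200),
    ("Borealis", "hybrid", "unconstrained", "fixed", 0.019, 1200),
    ("Cairn", "cemented", "unconstrained", "fixed", 0.020, 7000),
    ("Cairn", "cemented", "posterior_stabilised", "fixed", 0.028, 3200),
    ("Dorsa", "cemented", "unconstrained", "fixed", 0.023, 5200),
    ("Dorsa", "uncemented", "unconstrained", "mobile", 0.030, 1800),
    ("Elan", "cemented", "unconstrained", "fixed", 0.018, 4200),
    ("Elan", "cemented", "unconstrained", "mobile", 0.035, 1500),
    ("Fenrir", "cemented", "posterior_stabilised", "fixed", 0.031, 2600),
    ("Fenrir", "cemented", "posterior_stabilised", "mobile", 0.040, 900),
    ("Glacier", "cemented", "unconstrained", "fixed", 0.021, 3800),
    ("Glacier", "monobloc", "unconstrained", "fixed", 0.017, 1400),
    ("Harrier", "cemented", "unconstrained", "fixed", 0.033, 2900),
    ("Harrier", "uncemented", "unconstrained", "fixed", 0.042, 1100),
    ("Isled", "cemented", "unconstrained", "fixed", 0.050, 1600),
    ("Isled", "hybrid", "unconstrained", "fixed", 0.038, 700),
]

_UKR_MENU = [
    ("Kestrel Partial", "mobile", 0.055, 9000),
    ("Kestrel Partial", "fixed", 0.042, 1600),
    ("Lyric Uni", "fixed", 0.048, 2400),
    ("Merlin Uni", "fixed", 0.065, 1400),
    ("Merlin Uni", "mobile", 0.090, 900),
    ("Nimbus Uni", "fixed", 0.120, 600),
]


def scenario_like_paper(seed: int = 0) -> RegistryScenario:
    """Bundled default scenario shaped like a national knee registry.

    About twenty total-knee constructs with true 5-year failures from
    1.2% to 5%, six unicondylar constructs from 4.2% to 12%, and one
    dominant low-failure construct with >=30000 procedures that is the
    intended benchmark; accrual runs April 2003 to end-2016 with
    administrative censoring at end-2016.
    """
    horizon = 2017.0 - 2003.25
    scenarios = []
    for brand, fixation, constraint, bearing, f5, n in _TKR_MENU:
        key = ConstructKey(brand, fixation, constraint, bearing, "TKR")
        scenarios.append(
            ConstructScenario(key, n, _const_hazard_for_failure(f5, horizon))
        )
    for brand, bearing, f5, n in _UKR_MENU:
        key = ConstructKey(brand, "cemented", "unicondylar", bearing, "UKR")
        scenarios.append(
            ConstructScenario(key, n, _const_hazard_for_failure(f5, horizon))
        )
    return RegistryScenario(scenarios=tuple(scenarios), seed=seed)
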