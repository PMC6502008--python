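"""Domain model for knee-replacement registry procedures.

A *construct* — the unit of comparison throughout the package — is a
specific combination of implant brand, fixation method, degree of
constraint and bearing mobility.  Registry analyses treat every distinct
combination as a separate product, because fixation, constraint and
bearing are each known to influence revision rates.

Procedure records carry one row per primary knee replacement with the
time from the primary operation to the first linked revision, to death,
or to administrative censoring at the registry extract date.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Fixation",
    "Constraint",
    "Bearing",
    "Klass",
    "Gender",
    "EventType",
    "ConstructKey",
    "ProcedureRecord",
    "Stratum",
    "ExclusionLog",
    "EXCLUSION_REASONS",
    "PROCEDURE_COLUMNS",
    "apply_exclusions",
    "assign_stratum",
    "stratum_mask",
    "records_to_frame",
    "frame_to_records",
]


class Fixation(enum.StrEnum):
    CEMENTED = "cemented"
    UNCEMENTED = "uncemented"
    HYBRID = "hybrid"
    MONOBLOC = "monobloc"


class Constraint(enum.StrEnum):
    UNCONSTRAINED = "unconstrained"
    POSTERIOR_STABILISED = "posterior_stabilised"
    UNICONDYLAR = "unicondylar"


class Bearing(enum.StrEnum):
    FIXED = "fixed"
    MOBILE = "mobile"


class Klass(enum.StrEnum):
    """Total (TKR) versus unicondylar / partial (UKR) knee replacement."""

    TKR = "TKR"
    UKR = "UKR"


class Gender(enum.StrEnum):
    MALE = "male"
    FEMALE = "female"
    MISSING = "missing"


class EventType(enum.StrEnum):
    """Outcome terminating follow-up.

    Revision (the failure event) is any addition, removal or modification
    of an implant in a joint that previously underwent replacement; death
    and the administrative extract date both act as censoring.
    """

    REVISION = "revision"
    DEATH = "death"
    ADMINISTRATIVE = "administrative"


@dataclass(frozen=True, slots=True)
class ConstructKey:
    """Identity of one construct: brand x fixation x constraint x bearing.

    Equality is field-wise; every distinct combination is a distinct
    construct.  The class (TKR/UKR) is redundant with constraint —
    unicondylar constraint defines a UKR — and is validated as such.
    """

    brand: str
    fixation: Fixation
    constraint: Constraint
    bearing: Bearing
    klass: Klass

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixation", Fixation(self.fixation))
        object.__setattr__(self, "constraint", Constraint(self.constraint))
        object.__setattr__(self, "bearing", Bearing(self.bearing))
        object.__setattr__(self, "klass", Klass(self.klass))
        is_uni = self.constraint is Constraint.UNICONDYLAR
        if is_uni != (self.klass is Klass.UKR):
            raise ValueError(
                f"class {self.klass} inconsistent with constraint {self.constraint}: "
                "a construct is a UKR iff its constraint is unicondylar"
            )

    @property
    def label(self) -> str:
        if self.klass is Klass.UKR:
            return f"({self.klass}) {self.brand} Unicondylar, {self.bearing}"
        constraint = self.constraint.replace("_", "-")
        return f"({self.klass}) {self.brand} {self.fixation}, {constraint} {self.bearing}"

    def __str__(self) -> str:  # stable sort key for tie-breaking
        return self.label


@dataclass(slots=True)
class ProcedureRecord:
    """One primary knee replacement with follow-up outcome.

    ``time_years`` is the duration from the primary operation to the
    first linked revision, death, or administrative censoring, whichever
    comes first; ``event`` says which.  ``traceable`` is False when the
    patient could not be traced for mortality, ``valid_construct`` is
    False when fixation or constraint is unknown.
    """

    procedure_id: str
    construct: ConstructKey
    gender: Gender
    age_at_primary: float | None
    time_years: float
    event: EventType
    valid_construct: bool = True
    patellofemoral: bool = False
    traceable: bool = True

    def __post_init__(self) -> None:
        self.gender = Gender(self.gender)
        self.event = EventType(self.event)
        if self.time_years < 0:
            raise ValueError(f"time_years must be >= 0, got {self.time_years}")


# Age bands partition ages as [0, 55), [55, 75], (75, inf): the bands are
# printed "<55", "55-75", ">75", read literally so 55 and 75 both fall in
# the middle band.
_AGE_BANDS: dict[str, tuple[float, float]] = {
    "all": (-np.inf, np.inf),
    "under55": (-np.inf, 55.0),       # age < 55
    "from55to75": (55.0, np.inf),     # 55 <= age <= 75 (upper handled below)
    "over75": (75.0, np.inf),         # age > 75
}


@dataclass(frozen=True, slots=True)
class Stratum:
    """One analysis cell: a gender restriction crossed with an age band."""

    gender: str = "all"
    age_band: str = "all"

    def __post_init__(self) -> None:
        if self.gender not in ("all", "male", "female"):
            raise ValueError(f"unknown gender stratum {self.gender!r}")
        if self.age_band not in _AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")

    def contains(self, gender: str, age: float | None) -> bool:
        if self.gender != "all" and gender != self.gender:
            return False
        if self.age_band == "all":
            return True
        if age is None or (isinstance(age, float) and np.isnan(age)):
            return False
        if self.age_band == "under55":
            return age < 55.0
        if self.age_band == "from55to75":
            return 55.0 <= age <= 75.0
        return age > 75.0

    @property
    def label(self) -> str:
        g = "all" if self.gender == "all" else self.gender
        bands = {"all": "all ages", "under55": "<55", "from55to75": "55-75", "over75": ">75"}
        return f"{g}, {bands[self.age_band]}"


#: Canonical column order of the in-memory procedure table (and of the
#: procedure CSV; see :mod:`kneebench.io`).
PROCEDURE_COLUMNS = [
    "procedure_id",
    "brand",
    "fixation",
    "constraint",
    "bearing",
    "klass",
    "gender",
    "age_at_primary",
    "time_years",
    "event",
    "valid_construct",
    "patellofemoral",
    "traceable",
]

#: Fixed order in which exclusion reasons are tested; a record failing
#: several is counted once, under the first reason that applies.
EXCLUSION_REASONS = ["demographics", "untraceable", "invalid_construct", "patellofemoral"]


@dataclass(slots=True)
class ExclusionLog:
    """Counts of records removed, one bucket per exclusion reason."""

    demographics: int = 0
    untraceable: int = 0
    invalid_construct: int = 0
    patellofemoral: int = 0

    def as_dict(self) -> dict[str, int]:
        return {r: getattr(self, r) for r in EXCLUSION_REASONS}

    @property
    def total(self) -> int:
        return sum(self.as_dict().values())


def records_to_frame(records: Iterable[ProcedureRecord]) -> pd.DataFrame:
    """Flatten ProcedureRecord objects into the canonical procedure table."""
    rows = []
    for r in records:
        rows.append(
            {
                "procedure_id": r.procedure_id,
                "brand": r.construct.brand,
                "fixation": str(r.construct.fixation),
                "constraint": str(r.construct.constraint),
                "bearing": str(r.construct.bearing),
                "klass": str(r.construct.klass),
                "gender": str(r.gender),
                "age_at_primary": np.nan if r.age_at_primary is None else float(r.age_at_primary),
                "time_years": float(r.time_years),
                "event": str(r.event),
                "valid_construct": bool(r.valid_construct),
                "patellofemoral": bool(r.patellofemoral),
                "traceable": bool(r.traceable),
            }
        )
    df = pd.DataFrame(rows, columns=PROCEDURE_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[ProcedureRecord]:
    """Inverse of :func:`records_to_frame` (rows with unknown fixation or
    constraint come back with a placeholder construct and
    ``valid_construct=False``)."""
    out: list[ProcedureRecord] = []
    for row in df.itertuples(index=False):
        valid = bool(getattr(row, "valid_construct", True))
        try:
            construct = ConstructKey(row.brand, row.fixation, row.constraint, row.bearing, row.klass)
        except ValueError:
            if valid:
                raise
            construct = ConstructKey(row.brand, "cemented", "unconstrained", "fixed", "TKR")
        age = row.age_at_primary
        out.append(
            ProcedureRecord(
                procedure_id=str(row.procedure_id),
                construct=construct,
                gender=Gender(row.gender),
                age_at_primary=None if pd.isna(age) else float(age),
                time_years=float(row.time_years),
                event=EventType(row.event),
                valid_construct=valid,
                patellofemoral=bool(getattr(row, "patellofemoral", False)),
                traceable=bool(getattr(row, "traceable", True)),
            )
        )
    return out


def _ensure_frame(records) -> tuple[pd.DataFrame, bool]:
    if isinstance(records, pd.DataFrame):
        return records, True
    return records_to_frame(records), False


def apply_exclusions(records) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the registry inclusion criteria.

    Removes procedures with missing gender or age, untraceable mortality
    status, unknown fixation/constraint, and patellofemoral replacements —
    in that order of precedence, each record counted once under the first
    reason that applies.

    Parameters
    ----------
    records : DataFrame or iterable of ProcedureRecord
        The raw procedure table.

    Returns
    -------
    included : DataFrame
        Rows passing every criterion, original order preserved.
    log : ExclusionLog
        Removed-record counts per reason; ``included`` plus ``log.total``
        always equals the input size.
    """
    df, _ = _ensure_frame(records)
    if len(df) == 0:
        return df.copy(), ExclusionLog()

    gender = df["gender"].astype(str)
    missing_demo = gender.eq("missing") | gender.isin(("nan", "")) | df["age_at_primary"].isna()
    untraceable = ~df["traceable"].astype(bool)
    invalid = ~df["valid_construct"].astype(bool)
    patellofemoral = df["patellofemoral"].astype(bool)

    reason = np.full(len(df), "", dtype=object)
    for name, mask in [
        ("demographics", missing_demo.to_numpy()),
        ("untraceable", untraceable.to_numpy()),
        ("invalid_construct", invalid.to_numpy()),
        ("patellofemoral", patellofemoral.to_numpy()),
    ]:
        reason[(reason == "") & mask] = name

    log = ExclusionLog(**{r: int((reason == r).sum()) for r in EXCLUSION_REASONS})
    included = df.loc[reason == ""].copy()
    return included, log


def assign_stratum(record, stratum: Stratum) -> bool:
    """True iff the (already included) record belongs to the stratum."""
    if isinstance(record, ProcedureRecord):
        return stratum.contains(str(record.gender), record.age_at_primary)
    return stratum.contains(str(record.gender), record.age_at_primary)


def stratum_mask(df: pd.DataFrame, stratum: Stratum, *, integer_ages: bool = False) -> pd.Series:
    """Vectorised stratum membership over a procedure table.

    ``integer_ages`` truncates ages to whole years before banding, for
    registries that record age as completed years; off by default.
    """
    mask = pd.Series(True, index=df.index)
    if stratum.gender != "all":
        mask &= df["gender"].astype(str) == stratum.gender
    if stratum.age_band != "all":
        age = df["age_at_primary"].astype(float)
        if integer_ages:
            age = np.floor(age)
        if stratum.age_band == "under55":
            mask &= age < 55.0
        elif stratum.age_band == "from55to75":
            mask &= (age >= 55.0) & (age <= 75.0)
        else:
            mask &= age > 75.0
        mask &= age.notna()
    return mask
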