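"""Benchmark selection, margin testing and equivalence classification.

Within each stratum and at each evaluation time, the *benchmark* is the
construct with the lowest estimated net failure among those with at
least 1000 procedures still at risk — enough volume that the benchmark's
own confidence interval is about +/-1.5%, tight enough to serve as a
reference standard.

Every other construct is then compared with the benchmark through the
difference in failure proportions.  Two non-inferiority margins are
carried: a conservative 20% relative increase in failure over the
benchmark, and a 100% increase (a doubling), both converted to the
absolute-difference scale as delta = relative x F_ref.

Classification follows the confidence-interval rule:

* upper CI <= delta_20            -> non-inferior
* lower CI >  delta_100           -> inferior by >= 100%
* lower CI >  delta_20            -> inferior by >= 20%
* otherwise                       -> inconclusive (non-inferiority not shown)
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

from scipy.stats import norm

from .survival import KMEstimate

__all__ = [
    "Z_95",
    "Margin",
    "Status",
    "ComparisonResult",
    "NoBenchmarkAvailable",
    "DegenerateComparison",
    "select_benchmark",
    "compare",
    "classify",
]

#: Two-sided 95% normal multiplier.
Z_95 = 1.959964


class NoBenchmarkAvailable(Exception):
    """No construct meets the at-risk requirement in this stratum/time."""


class DegenerateComparison(Exception):
    """Pooled SE is zero while the difference is not; no test possible."""


@dataclass(frozen=True, slots=True)
class Margin:
    """A non-inferiority margin as a proportionate increase in risk."""

    relative: float

    def __post_init__(self) -> None:
        if self.relative <= 0:
            raise ValueError("margin must be a positive relative increase")

    def absolute_at(self, f_ref: float) -> float:
        """delta on the failure scale: relative x reference failure."""
        if f_ref < 0:
            raise ValueError("reference failure must be non-negative")
        return self.relative * f_ref


class Status(enum.StrEnum):
    NON_INFERIOR = "non_inferior"
    INCONCLUSIVE = "inconclusive"
    INFERIOR_20 = "inferior_20"
    INFERIOR_100 = "inferior_100"

    @property
    def printed(self) -> str:
        return _PRINTED[self]


_PRINTED = {
    Status.NON_INFERIOR: "Non-inferior",
    Status.INCONCLUSIVE: "Non-inferiority not shown",
    Status.INFERIOR_20: "Inferior by >=20%",
    Status.INFERIOR_100: "Inferior by >=100%",
}


@dataclass(frozen=True, slots=True)
class ComparisonResult:
    """One construct-versus-benchmark comparison at a fixed time.

    All failure quantities are proportions; percent rendering happens at
    the reporting layer.  ``p_value`` is the one-sided upper-tail normal
    probability of |diff| / se_diff (the convention the printed tables
    follow); ``p_noninf`` is the tail probability of the margin-shifted
    statistic ``z_noninf``.
    """

    comparator: Hashable
    reference: Hashable
    t: float
    f_xi: float
    f_ref: float
    diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    delta_20: float
    delta_100: float
    z_noninf: float
    p_value: float
    p_noninf: float
    status: Status
    n_at_risk: int
    margin_undefined: bool = False


def select_benchmark(
    estimates: Mapping[Hashable, KMEstimate] | Iterable[tuple[Hashable, KMEstimate]],
    min_at_risk: int = 1000,
) -> Hashable:
    """Pick the benchmark construct for one stratum and time.

    Returns the construct with the lowest estimated failure among those
    with ``n_at_risk_at_t >= min_at_risk``.  Exact ties on failure are
    broken in favour of the larger at-risk count (the tighter reference),
    then by the lexicographic construct label for determinism.

    Raises
    ------
    NoBenchmarkAvailable
        If no construct meets the at-risk requirement; callers record
        the stratum as unanalysable.
    """
    items = list(estimates.items()) if isinstance(estimates, Mapping) else list(estimates)
    eligible = [(k, e) for k, e in items if e.n_at_risk_at_t >= min_at_risk]
    if not eligible:
        raise NoBenchmarkAvailable(
            f"no construct has >= {min_at_risk} procedures at risk"
        )
    key, _ = min(eligible, key=lambda ke: (ke[1].failure, -ke[1].n_at_risk_at_t, str(ke[0])))
    return key


def classify(ci_low: float, ci_high: float, delta_20: float, delta_100: float) -> Status:
    """Equivalence status from the difference CI and the two margins.

    The strongest applicable label is returned: a lower bound above the
    100% margin implies the 20% condition as well, and is reported as
    inferior by >= 100%.
    """
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    if not (0 <= delta_20 <= delta_100):
        raise ValueError("margins must satisfy 0 <= delta_20 <= delta_100")
    if ci_high <= delta_20:
        return Status.NON_INFERIOR
    if ci_low > delta_100:
        return Status.INFERIOR_100
    if ci_low > delta_20:
        return Status.INFERIOR_20
    return Status.INCONCLUSIVE


def compare(
    comparator: KMEstimate,
    reference: KMEstimate,
    *,
    comparator_key: Hashable = "comparator",
    reference_key: Hashable = "reference",
    margins: tuple[float, float] = (0.20, 1.00),
    z_multiplier: float = Z_95,
    printed_sign: bool = False,
) -> ComparisonResult:
    """Test one construct against the benchmark at a common time.

    ``diff = F_xi - F_ref`` with pooled SE ``sqrt(GSE_xi^2 + GSE_ref^2)``
    and symmetric 95% CI ``diff +/- z * se``.  ``z_noninf`` is the
    margin-shifted statistic ``(diff - delta_20)/se``; ``printed_sign``
    flips the shift to ``+delta_20`` for consumers reproducing historical
    output that used the additive form.

    A reference failure of zero collapses both relative margins to zero;
    the comparison is then flagged ``margin_undefined`` (classification
    still follows the CI rule, degenerately strict).
    """
    if comparator.t != reference.t:
        raise ValueError(f"estimates at different times: {comparator.t} vs {reference.t}")
    m20, m100 = (Margin(margins[0]), Margin(margins[1]))
    if m20.relative > m100.relative:
        raise ValueError("margins must be ordered (small, large)")

    diff = comparator.failure - reference.failure
    se = math.hypot(comparator.gse, reference.gse)
    if se == 0.0 and diff != 0.0:
        raise DegenerateComparison("zero pooled SE with a non-zero difference")

    d20 = m20.absolute_at(reference.failure)
    d100 = m100.absolute_at(reference.failure)
    margin_undefined = reference.failure == 0.0

    half = z_multiplier * se
    ci_low, ci_high = diff - half, diff + half

    if se > 0:
        z_plain = diff / se
        shift = d20 if printed_sign else -d20
        z_noninf = (diff + shift) / se
        p_value = float(norm.sf(abs(z_plain)))
        p_noninf = float(norm.cdf((diff - d20) / se))
    else:  # diff == 0 here
        z_noninf = 0.0
        p_value = 0.5
        p_noninf = 0.5

    status = classify(ci_low, ci_high, d20, d100)
    return ComparisonResult(
        comparator=comparator_key,
        reference=reference_key,
        t=comparator.t,
        f_xi=comparator.failure,
        f_ref=reference.failure,
        diff=diff,
        se_diff=se,
        ci_low=ci_low,
        ci_high=ci_high,
        delta_20=d20,
        delta_100=d100,
        z_noninf=z_noninf,
        p_value=p_value,
        p_noninf=p_noninf,
        status=status,
        n_at_risk=comparator.n_at_risk_at_t,
        margin_undefined=margin_undefined,
    )
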