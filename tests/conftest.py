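import numpy as np
import pandas as pd
import pytest

from kneebench.registry import PROCEDURE_COLUMNS


def make_procedures(times, events, *, brand="Atlas", fixation="cemented",
                    constraint="unconstrained", bearing="fixed", klass="TKR",
                    gender="female", age=70.0, start=0) -> pd.DataFrame:
    """Minimal procedure table for one construct."""
    n = len(times)
    genders = [gender] * n if isinstance(gender, str) else list(gender)
    ages = [age] * n if np.isscalar(age) or age is None else list(age)
    return pd.DataFrame(
        {
            "procedure_id": [f"P{start + i:05d}" for i in range(n)],
            "brand": brand,
            "fixation": fixation,
            "constraint": constraint,
            "bearing": bearing,
            "klass": klass,
            "gender": genders,
            "age_at_primary": ages,
            "time_years": np.asarray(times, dtype=float),
            "event": list(events),
            "valid_construct": True,
            "patellofemoral": False,
            "traceable": True,
        }
    )[PROCEDURE_COLUMNS]


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
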