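import numpy as np
import pandas as pd
import pytest

from rwcea.cohort import ARM_COMPARATOR, ARM_FOCAL, CohortTable


def make_patients(rows: list[dict]) -> pd.DataFrame:
    """Build a patients frame from partial row dicts, filling valid defaults."""
    defaults = {
        "arm": ARM_COMPARATOR,
        "death_day": np.nan,
        "censor_day": np.nan,
        "eot_day": np.nan,
        "diagnosis_to_index_days": 30.0,
        "resident_flag": 1.0,
        "income_quintile": 3.0,
        "rurality": 0.0,
        "extent_of_disease": "metastatic",
        "ecog": 1.0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["patient_id"] = f"P{i:03d}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


def empty_costs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=str),
            "interval_index": pd.Series(dtype=int),
            "component": pd.Series(dtype=str),
            "amount": pd.Series(dtype=float),
        }
    )


def make_cohort(rows: list[dict], costs: pd.DataFrame | None = None, **kw) -> CohortTable:
    return CohortTable(
        make_patients(rows), costs if costs is not None else empty_costs(), **kw
    )


@pytest.fixture
def km_toy_cohort() -> CohortTable:
    """Four patients: censored at day 10 and 20, deaths at day 15 and 25.

    Hand Kaplan-Meier of the censoring distribution: risk set 4 at t=10
    (drop to 3/4), risk set 2 at t=20 (drop to 3/8).
    """
    return make_cohort(
        [
            {"censor_day": 10.0, "eot_day": 5.0},
            {"death_day": 15.0, "eot_day": 5.0},
            {"censor_day": 20.0, "eot_day": 5.0},
            {"death_day": 25.0, "eot_day": 5.0},
        ]
    )
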