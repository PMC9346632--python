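"""Cohort data model, CSV I/O and eligibility filtering.

A cohort is a pair of tables: ``patients`` (one row per subject; baseline
covariates plus the event timeline in integer days from the index date) and
``costs`` (long format: one row per patient x 30-day interval x cost
component). Day 0 is treatment initiation; calendar dates are never stored.

The two treatment arms are labelled ``focal`` (the strategy under evaluation,
a gemcitabine+nab-paclitaxel-like regimen) and ``comparator`` (a
FOLFIRINOX-like regimen).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

#: analysis horizon: 5 years of 365.25 days, rounded down
HORIZON_DAYS = 1826
#: partitioning interval for the censoring-adjusted estimators
INTERVAL_DAYS = 30
DAYS_PER_YEAR = 365.25

ARM_FOCAL = "focal"
ARM_COMPARATOR = "comparator"
ARMS = (ARM_FOCAL, ARM_COMPARATOR)

#: the nine cost components tracked per patient
COST_COMPONENTS = (
    "systemic_therapy_drug_acquisition",
    "acute_inpatient_hospitalization",
    "physician_services",
    "ambulatory_cancer_care",
    "emergency_department_visits",
    "hospital_outpatient_clinic",
    "outpatient_oral_drug_acquisition",
    "home_care_services",
    "other",
)

#: columns every patients.csv must carry, in this order (extra covariate
#: columns may follow)
PATIENT_REQUIRED = ("patient_id", "arm", "death_day", "censor_day", "eot_day")
#: columns of costs.csv
COST_COLUMNS = ("patient_id", "interval_index", "component", "amount")

@dataclass
class CohortTable:
    """A patient table plus its long-format cost stream.

    ``patients`` must have unique ``patient_id`` values and, per patient,
    exactly one of ``death_day``/``censor_day`` non-missing; that value bounds
    follow-up. ``eot_day`` (end of treatment, the progression proxy) never
    exceeds the observed end.
    """

    patients: pd.DataFrame
    costs: pd.DataFrame
    horizon_days: int = HORIZON_DAYS
    component_names: tuple[str, ...] = COST_COMPONENTS

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.patients["patient_id"].to_numpy()

    @property
    def focal(self) -> np.ndarray:
        """Boolean mask: True for the focal arm."""
        return (self.patients["arm"] == ARM_FOCAL).to_numpy()

    @property
    def died(self) -> np.ndarray:
        return self.patients["death_day"].notna().to_numpy()

    @property
    def observed_end(self) -> np.ndarray:
        """Follow-up bound per patient: death day if died, else censoring day."""
        d = self.patients["death_day"].to_numpy(dtype=float)
        c = self.patients["censor_day"].to_numpy(dtype=float)
        return np.where(np.isnan(d), c, d)

    @property
    def eot_day(self) -> np.ndarray:
        return self.patients["eot_day"].to_numpy(dtype=float)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        p = self.patients
        missing = [c for c in PATIENT_REQUIRED if c not in p.columns]
        if missing:
            raise SchemaError(f"patients table missing columns: {missing}")
        dup = p["patient_id"][p["patient_id"].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicate patient_id: {dup.iloc[0]!r}")
        bad_arm = ~p["arm"].isin(ARMS)
        if bad_arm.any():
            raise SchemaError(
                f"arm must be one of {ARMS}; got "
                f"{p.loc[bad_arm, 'arm'].iloc[0]!r}"
            )
        d = p["death_day"].notna()
        c = p["censor_day"].notna()
        both = d & c
        neither = ~d & ~c
        if both.any():
            raise SchemaError(
                "exactly one of death_day/censor_day must be set; both set "
                f"for patient_id {p.loc[both, 'patient_id'].iloc[0]!r}"
            )
        if neither.any():
            raise SchemaError(
                "exactly one of death_day/censor_day must be set; neither set "
                f"for patient_id {p.loc[neither, 'patient_id'].iloc[0]!r}"
            )
        end = self.observed_end
        eot = p["eot_day"].to_numpy(dtype=float)
        bad = ~np.isnan(eot) & (eot > end)
        if bad.any():
            pid = p.loc[bad, "patient_id"].iloc[0]
            raise SchemaError(f"eot_day exceeds observed end for patient_id {pid!r}")

        q = self.costs
        missing = [col for col in COST_COLUMNS if col not in q.columns]
        if missing:
            raise SchemaError(f"costs table missing columns: {missing}")
        if len(q):
            unknown = ~q["patient_id"].isin(set(p["patient_id"]))
            if unknown.any():
                pid = q.loc[unknown, "patient_id"].iloc[0]
                raise SchemaError(f"costs reference unknown patient_id {pid!r}")
            if (q["amount"].to_numpy(dtype=float) < 0).any():
                raise SchemaError("cost amounts must be nonnegative")
            ii = q["interval_index"].to_numpy(dtype=float)
            if (ii < 0).any() or not np.allclose(ii, np.round(ii)):
                raise SchemaError("interval_index must be a nonnegative integer")
            unknown_comp = ~q["component"].isin(self.component_names)
            if unknown_comp.any():
                name = q.loc[unknown_comp, "component"].iloc[0]
                raise SchemaError(f"unknown cost component {name!r}")

    # -- subsetting --------------------------------------------------------
    def subset(self, mask: np.ndarray) -> "CohortTable":
        """Return the cohort restricted to ``mask`` (boolean over patients)."""
        keep = self.patients.loc[mask].reset_index(drop=True)
        kept_ids = set(keep["patient_id"])
        costs = self.costs[self.costs["patient_id"].isin(kept_ids)].reset_index(
            drop=True
        )
        return CohortTable(keep, costs, self.horizon_days, self.component_names)


def _empty_costs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=str),
            "interval_index": pd.Series(dtype=int),
            "component": pd.Series(dtype=str),
            "amount": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _to_numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    """Convert a string column to float, treating '' as missing.

    Any other unparseable token is rejected with the 1-based data row number
    (header is row 1).
    """
    raw = df[col].astype(str)
    out = pd.to_numeric(raw.mask(raw == ""), errors="coerce")
    bad = out.isna() & (raw != "")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path.name}: row {i + 2}, column {col!r}: cannot parse "
            f"{raw.iloc[i]!r} (missing values must be empty fields)"
        )
    return out


def read_cohort(path: str | Path, horizon_days: int = HORIZON_DAYS) -> CohortTable:
    """Read a cohort from a directory containing patients.csv and costs.csv.

    ``costs.csv`` may be absent or empty (cohort with empty cost streams).
    """
    path = Path(path)
    ppath = path / "patients.csv"
    if not ppath.exists():
        raise SchemaError(f"missing {ppath}")
    p = pd.read_csv(ppath, dtype=str, keep_default_na=False)
    missing = [c for c in PATIENT_REQUIRED if c not in p.columns]
    if missing:
        raise SchemaError(f"{ppath.name}: missing columns {missing}")
    for col in p.columns:
        if col in ("patient_id", "arm", "extent_of_disease"):
            continue
        # numeric if every non-empty entry parses; otherwise kept categorical
        raw = p[col].astype(str)
        parsed = pd.to_numeric(raw.mask(raw == ""), errors="coerce")
        if not (parsed.isna() & (raw != "")).any():
            p[col] = parsed
        else:
            p[col] = raw.mask(raw == "")
    if "extent_of_disease" in p.columns:
        p["extent_of_disease"] = p["extent_of_disease"].mask(
            p["extent_of_disease"] == ""
        )

    cpath = path / "costs.csv"
    if cpath.exists():
        q = pd.read_csv(cpath, dtype=str, keep_default_na=False)
        if len(q) == 0:
            q = _empty_costs()
        else:
            missing = [c for c in COST_COLUMNS if c not in q.columns]
            if missing:
                raise SchemaError(f"{cpath.name}: missing columns {missing}")
            q["interval_index"] = _to_numeric(q, "interval_index", cpath).astype(int)
            q["amount"] = _to_numeric(q, "amount", cpath)
    else:
        q = _empty_costs()
    return CohortTable(p, q, horizon_days=horizon_days)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write patients.csv and costs.csv under ``path`` (missing -> empty field)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(path / "patients.csv", index=False, na_rep="")
    cohort.costs.to_csv(path / "costs.csv", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Eligibility filtering
# ---------------------------------------------------------------------------

@dataclass
class EligibilityRules:
    """Which cohort-definition exclusions to apply, in application order.

    The order below is the narrative order of the study protocol this
    pipeline mirrors; it affects only per-rule counts, never the retained
    set. A record excluded by an earlier rule is not recounted by later
    rules.
    """

    treatment_before_diagnosis: bool = True  # index >= 60 days before diagnosis
    death_before_index: bool = True
    non_resident: bool = True
    missing_income: bool = True
    missing_rurality: bool = True
    missing_extent: bool = True
    ecog_2plus_or_missing: bool = True

    def rule_names(self) -> list[str]:
        return [f.name for f in dataclasses.fields(self) if getattr(self, f.name)]


def _rule_mask(p: pd.DataFrame, rule: str) -> np.ndarray:
    """Exclusion mask (True = excluded) for one named rule."""

    def col(name: str) -> pd.Series:
        if name not in p.columns:
            raise SchemaError(
                f"eligibility rule {rule!r} requires column {name!r}"
            )
        return p[name]

    if rule == "treatment_before_diagnosis":
        v = pd.to_numeric(col("diagnosis_to_index_days"), errors="coerce")
        return (v <= -60).to_numpy()
    if rule == "death_before_index":
        return (col("death_day") < 0).fillna(False).to_numpy()
    if rule == "non_resident":
        return (col("resident_flag") == 0).to_numpy()
    if rule == "missing_income":
        return col("income_quintile").isna().to_numpy()
    if rule == "missing_rurality":
        return col("rurality").isna().to_numpy()
    if rule == "missing_extent":
        return col("extent_of_disease").isna().to_numpy()
    if rule == "ecog_2plus_or_missing":
        v = col("ecog")
        return (v.isna() | (v >= 2)).to_numpy()
    raise ValueError(f"unknown rule {rule!r}")


def apply_eligibility(
    cohort: CohortTable, rules: EligibilityRules | None = None
) -> tuple[CohortTable, dict[str, int]]:
    """Apply the cohort-definition exclusions; return (retained, exclusion log).

    The log maps each applied rule, in order, to the number of records it
    newly removed. ``n_input == n_retained + sum(log.values())`` always.
    Filtering is idempotent.
    """
    rules = rules or EligibilityRules()
    p = cohort.patients
    alive = np.ones(len(p), dtype=bool)  # still retained
    log: dict[str, int] = {}
    for rule in rules.rule_names():
        excl = _rule_mask(p, rule) & alive
        log[rule] = int(excl.sum())
        alive &= ~excl
    return cohort.subset(alive), log
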