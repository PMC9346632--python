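"""Censoring-adjusted mean life-years, QALYs and component costs per arm.

All three estimands run through the same partitioned IPCW engine; they
differ only in the per-patient, per-interval quantity Q_ik:

* life-years: days alive in the interval / 365.25;
* QALYs: quality-weighted days alive, u_pre while on treatment (index to
  end-of-treatment day inclusive) and u_post afterwards;
* costs: recorded amounts per component per interval.

Means are discounted at an annual rate (default 1.5%) applied at interval
midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ARM_COMPARATOR, ARM_FOCAL, DAYS_PER_YEAR, CohortTable
from .errors import ConfigError
from .ipcw import IntervalGrid, IPCWWeightTable, ipcw_adjusted_mean, per_patient_totals
from .propensity import WeightedCohort

DISCOUNT_RATE = 0.015


@dataclass(frozen=True)
class UtilitySpec:
    """Health utility weights: u_pre on treatment, u_post after end of treatment."""

    u_pre: float = 0.8
    u_post: float = 0.73

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_post <= self.u_pre <= 1.0):
            raise ConfigError(
                f"require 0 <= u_post <= u_pre <= 1; got u_pre={self.u_pre}, "
                f"u_post={self.u_post}"
            )


def alive_days_matrix(
    observed_end: np.ndarray, died: np.ndarray, grid: IntervalGrid
) -> np.ndarray:
    """Days alive per patient per interval (fractional days credited at death).

    Censored patients are alive through every interval they fully observe;
    intervals past their censoring time carry completeness 0 downstream, so
    the (unknowable) value there is irrelevant.
    """
    end = np.asarray(observed_end, dtype=float)[:, None]
    died = np.asarray(died, dtype=bool)[:, None]
    life_end = np.where(died, end, np.inf)
    return np.clip(
        np.minimum(life_end, grid.ends[None, :]) - grid.starts[None, :],
        0.0,
        grid.lengths[None, :],
    )


def life_years_matrix(cohort: CohortTable, grid: IntervalGrid) -> np.ndarray:
    return alive_days_matrix(cohort.observed_end, cohort.died, grid) / DAYS_PER_YEAR


def qaly_matrix_from_arrays(
    observed_end: np.ndarray,
    died: np.ndarray,
    eot_day: np.ndarray,
    grid: IntervalGrid,
    utilities: UtilitySpec,
) -> np.ndarray:
    """Quality-adjusted years per interval: split alive days at the EOT day."""
    eot = np.asarray(eot_day, dtype=float)
    if np.isnan(eot).any():
        bad = list(np.flatnonzero(np.isnan(eot))[:10])
        raise ConfigError(f"eot_day missing for patient row(s) {bad}")
    alive = alive_days_matrix(observed_end, died, grid)
    on_days = np.clip(eot[:, None] - grid.starts[None, :], 0.0, alive)
    off_days = alive - on_days
    return (utilities.u_pre * on_days + utilities.u_post * off_days) / DAYS_PER_YEAR


def qaly_matrix(
    cohort: CohortTable, grid: IntervalGrid, utilities: UtilitySpec
) -> np.ndarray:
    return qaly_matrix_from_arrays(
        cohort.observed_end, cohort.died, cohort.eot_day, grid, utilities
    )


def cost_matrices(cohort: CohortTable, grid: IntervalGrid) -> dict[str, np.ndarray]:
    """Per-component (n, K) cost matrices from the long cost stream."""
    n, k = cohort.n, grid.n_intervals
    q = cohort.costs
    if len(q) and (q["amount"].to_numpy(dtype=float) < 0).any():
        raise ConfigError("negative cost amounts")
    pid_index = pd.Series(np.arange(n), index=cohort.patient_ids)
    out = {name: np.zeros((n, k)) for name in cohort.component_names}
    if len(q) == 0:
        return out
    rows = pid_index[q["patient_id"]].to_numpy()
    cols = q["interval_index"].to_numpy(dtype=int)
    if (cols >= k).any():
        bad = int(cols[cols >= k][0])
        raise ConfigError(f"cost interval_index {bad} outside grid (K={k})")
    amounts = q["amount"].to_numpy(dtype=float)
    comp = q["component"].to_numpy()
    for name in cohort.component_names:
        mask = comp == name
        np.add.at(out[name], (rows[mask], cols[mask]), amounts[mask])
    return out


def _arm_means(
    quantity: np.ndarray,
    ipcw: IPCWWeightTable,
    weighted: WeightedCohort,
    rate: float,
) -> dict[str, float]:
    return {
        ARM_FOCAL: ipcw_adjusted_mean(
            quantity, ipcw, weighted.weights, weighted.focal, rate
        ),
        ARM_COMPARATOR: ipcw_adjusted_mean(
            quantity, ipcw, weighted.weights, ~weighted.focal, rate
        ),
    }


def life_years(
    cohort: CohortTable,
    grid: IntervalGrid,
    ipcw: IPCWWeightTable,
    weighted: WeightedCohort,
    rate: float = DISCOUNT_RATE,
) -> dict[str, float]:
    """Discounted, censoring-adjusted mean life-years per arm."""
    return _arm_means(life_years_matrix(cohort, grid), ipcw, weighted, rate)


def qalys(
    cohort: CohortTable,
    grid: IntervalGrid,
    ipcw: IPCWWeightTable,
    weighted: WeightedCohort,
    utilities: UtilitySpec = UtilitySpec(),
    rate: float = DISCOUNT_RATE,
) -> dict[str, float]:
    """Discounted, censoring-adjusted mean QALYs per arm."""
    return _arm_means(qaly_matrix(cohort, grid, utilities), ipcw, weighted, rate)


def costs(
    cohort: CohortTable,
    grid: IntervalGrid,
    ipcw: IPCWWeightTable,
    weighted: WeightedCohort,
    rate: float = DISCOUNT_RATE,
) -> dict[str, dict[str, float]]:
    """Per-arm discounted mean cost per component plus the component sum."""
    mats = cost_matrices(cohort, grid)
    out: dict[str, dict[str, float]] = {arm: {} for arm in (ARM_FOCAL, ARM_COMPARATOR)}
    for name, mat in mats.items():
        means = _arm_means(mat, ipcw, weighted, rate)
        for arm in out:
            out[arm][name] = means[arm]
    for arm in out:
        out[arm]["total"] = float(sum(out[arm][c] for c in cohort.component_names))
    return out


@dataclass
class ArmSummary:
    """Discounted mean outcomes for one arm."""

    arm: str
    mean_ly: float
    mean_qaly: float
    mean_cost_components: dict[str, float]
    mean_cost_total: float
    rate: float = DISCOUNT_RATE


def summarize_arms(
    cohort: CohortTable,
    grid: IntervalGrid,
    ipcw: IPCWWeightTable,
    weighted: WeightedCohort,
    utilities: UtilitySpec = UtilitySpec(),
    rate: float = DISCOUNT_RATE,
    discount_qalys: bool = True,
) -> dict[str, ArmSummary]:
    ly = life_years(cohort, grid, ipcw, weighted, rate)
    qa = qalys(cohort, grid, ipcw, weighted, utilities, rate if discount_qalys else 0.0)
    cc = costs(cohort, grid, ipcw, weighted, rate)
    return {
        arm: ArmSummary(
            arm=arm,
            mean_ly=ly[arm],
            mean_qaly=qa[arm],
            mean_cost_components={
                c: cc[arm][c] for c in cohort.component_names
            },
            mean_cost_total=cc[arm]["total"],
            rate=rate,
        )
        for arm in (ARM_FOCAL, ARM_COMPARATOR)
    }


def incremental(summary_focal: ArmSummary, summary_comparator: ArmSummary) -> dict:
    """Focal-minus-comparator deltas for cost (total and per component), LY, QALY."""
    return {
        "delta_cost_total": summary_focal.mean_cost_total
        - summary_comparator.mean_cost_total,
        "delta_cost_components": {
            c: summary_focal.mean_cost_components[c]
            - summary_comparator.mean_cost_components[c]
            for c in summary_focal.mean_cost_components
        },
        "delta_ly": summary_focal.mean_ly - summary_comparator.mean_ly,
        "delta_qaly": summary_focal.mean_qaly - summary_comparator.mean_qaly,
    }


def summary_frame(summaries: dict[str, ArmSummary]) -> pd.DataFrame:
    """Cost/effect table: components + totals + LY + QALY by arm + incremental."""
    f, c = summaries[ARM_FOCAL], summaries[ARM_COMPARATOR]
    inc = incremental(f, c)
    rows = []
    rows.append(("mean_total_cost", f.mean_cost_total, c.mean_cost_total,
                 inc["delta_cost_total"]))
    for name in f.mean_cost_components:
        rows.append(
            (name, f.mean_cost_components[name], c.mean_cost_components[name],
             inc["delta_cost_components"][name])
        )
    rows.append(("mean_ly", f.mean_ly, c.mean_ly, inc["delta_ly"]))
    rows.append(("mean_qaly", f.mean_qaly, c.mean_qaly, inc["delta_qaly"]))
    return pd.DataFrame(
        rows, columns=["category", ARM_FOCAL, ARM_COMPARATOR, "incremental"]
    )
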