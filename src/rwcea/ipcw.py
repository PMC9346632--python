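"""Interval-partitioned inverse-probability-of-censoring weighting (IPCW).

Right censoring (administrative or loss to follow-up) makes naive means of
accrued quantities (survival time, costs) biased because long, expensive
follow-up is preferentially cut short. The partitioned estimator splits the
horizon into 30-day intervals, keeps an interval for a patient only when
their experience over it is fully observed (death is observation, not
censoring), and upweights retained intervals by the inverse probability of
remaining uncensored:

    mean = sum_k D_k * [ sum_i w_i * omega_ik * Q_ik ] / [ sum_i w_i ]

where ``Q_ik`` is the quantity accrued by patient ``i`` in interval ``k``,
``omega_ik = delta_ik / Khat_c(min(death_i, e_k)-)`` is the censoring weight
(``Khat_c`` the Kaplan-Meier survivor of the censoring distribution,
evaluated at the left limit), ``w_i`` an analysis weight (IPTW or matched
indicator) and ``D_k`` an annual-rate discount factor at the interval
midpoint.

Completeness convention: a patient who dies during interval k contributes
their partial-interval quantity with delta = 1; a patient censored during
interval k contributes nothing for k (partial pre-censoring accrual is
discarded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .cohort import DAYS_PER_YEAR, HORIZON_DAYS, INTERVAL_DAYS, CohortTable
from .errors import IdentifiabilityError


@dataclass(frozen=True)
class IntervalGrid:
    """Partition of [0, horizon) into fixed-length intervals (last one shorter)."""

    horizon_days: int = HORIZON_DAYS
    interval_days: int = INTERVAL_DAYS

    @property
    def n_intervals(self) -> int:
        return -(-self.horizon_days // self.interval_days)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_intervals) * self.interval_days

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.interval_days, self.horizon_days)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0


@dataclass
class CensoringSurvivor:
    """Step-function Kaplan-Meier estimate of P(censoring time > t).

    ``times`` are the jump locations (ascending, starting at 0) and
    ``values`` the survivor value just after each jump (right-continuous).
    """

    times: np.ndarray
    values: np.ndarray

    def at(self, t: np.ndarray | float) -> np.ndarray:
        """Right-continuous evaluation Khat_c(t)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.values[np.maximum(idx, 0)]

    def left_limit(self, t: np.ndarray | float) -> np.ndarray:
        """Left-limit evaluation Khat_c(t-): value just before t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left") - 1
        out = np.where(
            idx < 0, 1.0, self.values[np.maximum(idx, 0)]
        )
        return out


def censoring_km(observed_end: np.ndarray, died: np.ndarray) -> CensoringSurvivor:
    """Kaplan-Meier of the censoring distribution from follow-up arrays.

    Censoring is the event; deaths enter as censored observations of the
    censoring time. Lifelines' tie handling (subjects censored at t remain
    at risk for events at t) realises the convention that deaths at t are
    at risk for censoring events at t.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(observed_end, dtype=float), event_observed=~np.asarray(died))
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    values = sf.to_numpy(dtype=float)
    if times[0] != 0.0:  # lifelines always includes 0, but be safe
        times = np.insert(times, 0, 0.0)
        values = np.insert(values, 0, 1.0)
    return CensoringSurvivor(times=times, values=values)


def fit_censoring_survivor(cohort: CohortTable) -> CensoringSurvivor:
    """Fit the censoring survivor on a cohort (pooled across arms)."""
    return censoring_km(cohort.observed_end, cohort.died)


@dataclass
class IPCWWeightTable:
    """Per-patient, per-interval completeness indicators and censoring weights."""

    delta: np.ndarray  # (n, K) in {0, 1}
    omega: np.ndarray  # (n, K), 0 where delta == 0, >= 1 where delta == 1
    grid: IntervalGrid

    def to_frame(self, patient_ids: np.ndarray):
        """Long audit table (patient_id, interval, delta, omega)."""
        import pandas as pd

        n, k = self.delta.shape
        return pd.DataFrame(
            {
                "patient_id": np.repeat(patient_ids, k),
                "interval": np.tile(np.arange(k), n),
                "delta": self.delta.ravel().astype(int),
                "omega": self.omega.ravel(),
            }
        )


def ipcw_weights_from_arrays(
    observed_end: np.ndarray,
    died: np.ndarray,
    grid: IntervalGrid,
    survivor: CensoringSurvivor,
) -> IPCWWeightTable:
    """Compute delta_ik and omega_ik from follow-up arrays.

    delta_ik = 1 iff the patient was not censored before min(death_i, e_k):
    all intervals for deaths; intervals ending at or before the censoring
    time for censored patients. omega divides by the censoring survivor at
    the left limit of min(death_i, e_k) so a censoring event exactly at the
    evaluation time does not deflate its own weight.
    """
    end = np.asarray(observed_end, dtype=float)[:, None]
    died = np.asarray(died, dtype=bool)[:, None]
    e_k = grid.ends[None, :].astype(float)

    delta = np.where(died, True, end >= e_k)
    eval_t = np.where(died, np.minimum(end, e_k), e_k)
    kc = survivor.left_limit(eval_t)
    needed = delta & (kc <= 0.0)
    if needed.any():
        k_bad = int(np.argwhere(needed)[0][1])
        raise IdentifiabilityError(
            f"censoring survivor is 0 where a weight is needed "
            f"(interval {k_bad}, [{grid.starts[k_bad]}, {grid.ends[k_bad]}) days)"
        )
    omega = np.where(delta, 1.0 / np.where(kc > 0, kc, 1.0), 0.0)
    return IPCWWeightTable(delta=delta.astype(np.uint8), omega=omega, grid=grid)


def ipcw_weights(
    cohort: CohortTable, grid: IntervalGrid, survivor: CensoringSurvivor
) -> IPCWWeightTable:
    """Weight table for a cohort (survivor should be fitted on the same cohort)."""
    return ipcw_weights_from_arrays(cohort.observed_end, cohort.died, grid, survivor)


def discount_factors(grid: IntervalGrid, rate: float) -> np.ndarray:
    """Annual-compounding discount factor at each interval midpoint."""
    return (1.0 + rate) ** (-grid.midpoints / DAYS_PER_YEAR)


def per_patient_totals(
    quantity: np.ndarray, weights: IPCWWeightTable, rate: float = 0.0
) -> np.ndarray:
    """Discounted, censoring-weighted total per patient: sum_k D_k omega_ik Q_ik.

    The weighted mean of these totals over an arm equals the partitioned
    IPCW-adjusted mean, so the same per-patient numbers feed both arm-level
    summaries and per-patient net-monetary-benefit regression.
    """
    d = discount_factors(weights.grid, rate)
    return (np.asarray(quantity, dtype=float) * weights.omega * d[None, :]).sum(axis=1)


def ipcw_adjusted_mean(
    quantity: np.ndarray,
    weights: IPCWWeightTable,
    analysis_weights: np.ndarray,
    arm_mask: np.ndarray,
    rate: float = 0.0,
) -> float:
    """IPCW-adjusted, discounted, analysis-weighted mean over one arm."""
    w = np.asarray(analysis_weights, dtype=float)[arm_mask]
    if len(w) == 0 or w.sum() <= 0:
        raise ValueError("empty arm (no patients or zero total weight)")
    totals = per_patient_totals(quantity, weights, rate)[arm_mask]
    return float(np.sum(w * totals) / np.sum(w))
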