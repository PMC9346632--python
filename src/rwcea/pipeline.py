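"""End-to-end orchestration: cohort -> weights -> IPCW -> outcomes -> economics.

The pipeline is expressed over plain arrays so that bootstrap replicates can
resample patients and re-estimate every model (propensity fit, stabilized
weights or matching, censoring Kaplan-Meier, IPCW weight table) without
re-parsing data frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import ARM_COMPARATOR, ARM_FOCAL, CohortTable
from .econ import (
    CEResult,
    bootstrap_deltas,
    default_wtp_grid,
    evaluate_ce,
)
from .errors import ConfigError
from .ipcw import (
    IntervalGrid,
    censoring_km,
    ipcw_weights_from_arrays,
    per_patient_totals,
)
from .outcomes import (
    DISCOUNT_RATE,
    ArmSummary,
    UtilitySpec,
    cost_matrices,
    life_years_matrix,
    qaly_matrix_from_arrays,
)
from .propensity import (
    WeightedCohort,
    fit_propensity_design,
    design_matrix,
    psm_match,
    stabilized_weights,
    unit_weights,
)


@dataclass
class AnalysisSpec:
    """Choices that define one analysis run."""

    covariates: list[str]
    scheme: str = "iptw"  # "iptw" | "psm" | "crude"
    utilities: UtilitySpec = field(default_factory=UtilitySpec)
    discount_rate: float = DISCOUNT_RATE
    discount_qalys: bool = True
    grid: IntervalGrid = field(default_factory=IntervalGrid)
    caliper_sd: float = 0.2
    trim_scores: tuple[float, float] | None = None


@dataclass
class CohortArrays:
    """Precomputed numeric views of a cohort for (re-)estimation."""

    design: np.ndarray  # (n, p) propensity design
    design_columns: list[str]
    focal: np.ndarray
    observed_end: np.ndarray
    died: np.ndarray
    eot_day: np.ndarray
    ly_mat: np.ndarray  # (n, K) life-years per interval
    qaly_mat: np.ndarray
    cost_mat: np.ndarray  # (n, K) total cost per interval
    cost_mats: dict[str, np.ndarray]
    spec: AnalysisSpec

    @classmethod
    def from_cohort(cls, cohort: CohortTable, spec: AnalysisSpec) -> "CohortArrays":
        if spec.scheme == "crude":
            x = np.zeros((cohort.n, 0))
            cols: list[str] = []
        else:
            xdf = design_matrix(cohort.patients, spec.covariates)
            x, cols = xdf.to_numpy(), list(xdf.columns)
        mats = cost_matrices(cohort, spec.grid)
        total = np.zeros((cohort.n, spec.grid.n_intervals))
        for m in mats.values():
            total += m
        return cls(
            design=x,
            design_columns=cols,
            focal=cohort.focal,
            observed_end=cohort.observed_end,
            died=cohort.died,
            eot_day=cohort.eot_day,
            ly_mat=life_years_matrix(cohort, spec.grid),
            qaly_mat=qaly_matrix_from_arrays(
                cohort.observed_end, cohort.died, cohort.eot_day, spec.grid,
                spec.utilities,
            ),
            cost_mat=total,
            cost_mats=mats,
            spec=spec,
        )

    def take(self, idx: np.ndarray) -> "CohortArrays":
        return CohortArrays(
            design=self.design[idx],
            design_columns=self.design_columns,
            focal=self.focal[idx],
            observed_end=self.observed_end[idx],
            died=self.died[idx],
            eot_day=self.eot_day[idx],
            ly_mat=self.ly_mat[idx],
            qaly_mat=self.qaly_mat[idx],
            cost_mat=self.cost_mat[idx],
            cost_mats={},  # per-component detail not needed inside bootstrap
            spec=self.spec,
        )


@dataclass
class PatientLevel:
    """Per-patient discounted, censoring-weighted totals plus analysis weights."""

    weighted: WeightedCohort
    ly: np.ndarray
    qaly: np.ndarray
    cost: np.ndarray
    cost_components: dict[str, np.ndarray]
    propensity_scores: np.ndarray | None
    spec: AnalysisSpec

    @property
    def focal(self) -> np.ndarray:
        return self.weighted.focal

    @property
    def weights(self) -> np.ndarray:
        return self.weighted.weights

    def arm_mean(self, values: np.ndarray, arm: str) -> float:
        mask = self.focal if arm == ARM_FOCAL else ~self.focal
        w = self.weights[mask]
        if w.sum() <= 0:
            raise ConfigError(f"arm {arm!r} has zero total weight")
        return float(np.sum(w * values[mask]) / np.sum(w))

    def delta(self, values: np.ndarray) -> float:
        return self.arm_mean(values, ARM_FOCAL) - self.arm_mean(values, ARM_COMPARATOR)


def _weights_for(arrays: CohortArrays, match_seed: int) -> tuple[WeightedCohort, np.ndarray | None]:
    spec = arrays.spec
    if spec.scheme == "crude":
        return unit_weights(arrays.focal), None
    ps = fit_propensity_design(arrays.design, arrays.focal, arrays.design_columns)
    if spec.scheme == "iptw":
        return stabilized_weights(ps, trim=spec.trim_scores), ps.scores
    if spec.scheme == "psm":
        return psm_match(ps, caliper_sd=spec.caliper_sd, seed=match_seed), ps.scores
    raise ConfigError(f"unknown scheme {spec.scheme!r}")


def patient_level_from_arrays(
    arrays: CohortArrays, match_seed: int = 0
) -> PatientLevel:
    weighted, scores = _weights_for(arrays, match_seed)
    survivor = censoring_km(arrays.observed_end, arrays.died)
    table = ipcw_weights_from_arrays(
        arrays.observed_end, arrays.died, arrays.spec.grid, survivor
    )
    r = arrays.spec.discount_rate
    r_q = r if arrays.spec.discount_qalys else 0.0
    return PatientLevel(
        weighted=weighted,
        ly=per_patient_totals(arrays.ly_mat, table, r),
        qaly=per_patient_totals(arrays.qaly_mat, table, r_q),
        cost=per_patient_totals(arrays.cost_mat, table, r),
        cost_components={
            name: per_patient_totals(mat, table, r)
            for name, mat in arrays.cost_mats.items()
        },
        propensity_scores=scores,
        spec=arrays.spec,
    )


def patient_level(
    cohort: CohortTable, spec: AnalysisSpec, match_seed: int = 0
) -> PatientLevel:
    """Fit the full pipeline on a cohort and return per-patient contributions."""
    return patient_level_from_arrays(
        CohortArrays.from_cohort(cohort, spec), match_seed
    )


def arm_summaries(pl: PatientLevel, component_names=None) -> dict[str, ArmSummary]:
    """Arm-level discounted means assembled from per-patient totals."""
    comps = component_names or list(pl.cost_components)
    out = {}
    for arm in (ARM_FOCAL, ARM_COMPARATOR):
        comp_means = {c: pl.arm_mean(pl.cost_components[c], arm) for c in comps}
        out[arm] = ArmSummary(
            arm=arm,
            mean_ly=pl.arm_mean(pl.ly, arm),
            mean_qaly=pl.arm_mean(pl.qaly, arm),
            mean_cost_components=comp_means,
            mean_cost_total=pl.arm_mean(pl.cost, arm),
            rate=pl.spec.discount_rate,
        )
    return out


def run_ce(
    cohort: CohortTable,
    spec: AnalysisSpec,
    n_boot: int = 1000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> dict[str, CEResult]:
    """Point estimates plus whole-pipeline bootstrap, for LY and QALY effects.

    One bootstrap pass re-estimates the propensity model, weights (or
    matching), censoring survivor and IPCW table per replicate and records
    (dLY, dQALY, dCost) jointly, from which both CEResults are assembled.
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    arrays = CohortArrays.from_cohort(cohort, spec)
    ss = np.random.SeedSequence(seed)
    ss_match, ss_boot = ss.spawn(2)
    match_seed = int(ss_match.generate_state(1)[0] % (2**31))
    boot_seed = int(ss_boot.generate_state(1)[0] % (2**31))
    pl = patient_level_from_arrays(arrays, match_seed)

    rng_match = np.random.default_rng(ss_match)

    def estimator(idx: np.ndarray) -> tuple[float, float, float]:
        sub = arrays.take(idx)
        pl_b = patient_level_from_arrays(
            sub, match_seed=int(rng_match.integers(2**31))
        )
        return (pl_b.delta(pl_b.ly), pl_b.delta(pl_b.qaly), pl_b.delta(pl_b.cost))

    draws, redraws = bootstrap_deltas(
        estimator, len(arrays.focal), arrays.focal, n_boot=n_boot, seed=boot_seed
    )
    d_ly, d_qaly, d_cost = draws[:, 0], draws[:, 1], draws[:, 2]
    results = {}
    for label, effect, boot_eff in (
        ("ly", pl.ly, d_ly),
        ("qaly", pl.qaly, d_qaly),
    ):
        results[label] = evaluate_ce(
            effect_label=label,
            effect=effect,
            cost=pl.cost,
            focal=pl.focal,
            weights=pl.weights,
            boot_delta_effect=boot_eff,
            boot_delta_cost=d_cost,
            wtp_grid=wtp_grid,
            n_single_arm_redraws=redraws,
        )
    return results
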