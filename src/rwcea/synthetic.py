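"""Synthetic administrative-claims cohort generator with known ground truth.

The real cohort this pipeline was designed for lives behind a data-holding
institution and cannot be redistributed, so every downstream stage is
exercised on simulated cohorts that reproduce the *structure* of such data:

* baseline covariates (continuous / binary / categorical);
* confounded binary treatment assignment via a logistic model on the
  covariates;
* per-arm Weibull survival, optionally accelerated/decelerated by the same
  covariates (confounding by indication);
* an end-of-treatment day (the progression proxy) at a Uniform fraction of
  survival time;
* independent exponential censoring plus an administrative cutoff day;
* longitudinal cost accrual per 30-day interval across nine components,
  with on-treatment and terminal-phase cost elevation (the right-skewed,
  death-concentrated pattern of claims data).

All times are integer days from the index date. ``compute_truth`` supplies
the estimands the pipeline should recover: restricted mean survival per arm
(analytic Weibull integrals when survival does not depend on covariates,
otherwise a large-n Monte-Carlo oracle) and mean discounted cost per arm
(Monte-Carlo with censoring disabled, using expected per-interval accrual).
The oracle never calls the estimation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
from scipy import integrate

from .cohort import (
    ARM_COMPARATOR,
    ARM_FOCAL,
    DAYS_PER_YEAR,
    HORIZON_DAYS,
    INTERVAL_DAYS,
    CohortTable,
)
from .errors import ConfigError


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class Covariate:
    """One baseline covariate and its sampling distribution.

    kind 'continuous': params {mean, sd}; 'binary': params {p};
    'categorical': params {levels: [...], probs: [...]}.
    """

    name: str
    kind: str
    params: dict[str, Any]

    def validate(self) -> None:
        if self.kind == "continuous":
            if self.params.get("sd", 0) <= 0:
                raise ConfigError(f"covariate {self.name!r}: sd must be > 0")
        elif self.kind == "binary":
            p = self.params.get("p")
            if p is None or not (0 < p < 1):
                raise ConfigError(f"covariate {self.name!r}: p must be in (0,1)")
        elif self.kind == "categorical":
            levels = self.params.get("levels")
            probs = np.asarray(self.params.get("probs", []), dtype=float)
            if not levels or len(levels) != len(probs):
                raise ConfigError(
                    f"covariate {self.name!r}: levels/probs lengths differ"
                )
            if (probs <= 0).any() or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
                raise ConfigError(
                    f"covariate {self.name!r}: probs must be positive and sum to 1"
                )
        else:
            raise ConfigError(f"covariate {self.name!r}: unknown kind {self.kind!r}")

    def draw(self, rng: np.random.Generator, n: int):
        if self.kind == "continuous":
            return rng.normal(self.params["mean"], self.params["sd"], n)
        if self.kind == "binary":
            return (rng.random(n) < self.params["p"]).astype(float)
        return rng.choice(
            self.params["levels"], size=n, p=np.asarray(self.params["probs"])
        )


@dataclass
class SurvivalModel:
    """Weibull survival in days, with optional covariate acceleration.

    The per-patient scale is ``scale * exp(sum_j coef_j (x_j - center_j))``;
    with empty ``log_scale_coefs`` survival is pure per-arm Weibull and the
    restricted-mean truths are analytic. Coefficient keys are covariate
    names (or ``name=level`` for categorical indicators).
    """

    shape: float
    scale: float
    log_scale_coefs: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)

    def validate(self, arm: str) -> None:
        if self.shape <= 0:
            raise ConfigError(f"survival_model[{arm}].shape must be > 0")
        if self.scale <= 0:
            raise ConfigError(f"survival_model[{arm}].scale must be > 0")


@dataclass
class EndOfTreatmentModel:
    """End-of-treatment day as a Uniform fraction of survival time."""

    frac_low: float = 0.2
    frac_high: float = 0.8

    def validate(self, arm: str) -> None:
        if not (0.0 <= self.frac_low <= self.frac_high <= 1.0):
            raise ConfigError(
                f"eot_model[{arm}]: need 0 <= frac_low <= frac_high <= 1"
            )


@dataclass
class CensoringModel:
    """Independent exponential censoring plus an administrative cutoff day."""

    rate_per_day: float = 0.0
    admin_cutoff_day: int = HORIZON_DAYS

    def validate(self) -> None:
        if self.rate_per_day < 0:
            raise ConfigError("censoring_model.rate_per_day must be >= 0")
        if self.admin_cutoff_day < 1:
            raise ConfigError("censoring_model.admin_cutoff_day must be >= 1")


@dataclass
class CostComponentModel:
    """Lognormal per-interval accrual for one cost component.

    Means are unconditional expected amounts per fully-observed standard
    30-day interval, split by treatment state; ``terminal_mult`` scales the
    interval in which the patient dies; ``occur_p`` thins accrual to
    occasional events while preserving the stated mean.
    """

    name: str
    mean_on_focal: float = 0.0
    mean_on_comparator: float = 0.0
    mean_off_focal: float = 0.0
    mean_off_comparator: float = 0.0
    sigma_log: float = 0.8
    terminal_mult: float = 1.0
    occur_p: float = 1.0

    def validate(self) -> None:
        for f in ("mean_on_focal", "mean_on_comparator", "mean_off_focal",
                  "mean_off_comparator"):
            if getattr(self, f) < 0:
                raise ConfigError(f"cost component {self.name!r}: {f} must be >= 0")
        if self.sigma_log < 0:
            raise ConfigError(f"cost component {self.name!r}: sigma_log must be >= 0")
        if self.terminal_mult <= 0:
            raise ConfigError(f"cost component {self.name!r}: terminal_mult must be > 0")
        if not (0 < self.occur_p <= 1):
            raise ConfigError(f"cost component {self.name!r}: occur_p must be in (0,1]")

    def mean_on(self, arm: str) -> float:
        return self.mean_on_focal if arm == ARM_FOCAL else self.mean_on_comparator

    def mean_off(self, arm: str) -> float:
        return self.mean_off_focal if arm == ARM_FOCAL else self.mean_off_comparator


@dataclass
class SimulationConfig:
    """Full generator parameterisation; see module docstring."""

    n_patients: int
    covariates: list[Covariate]
    assignment_coefs: dict[str, float]  # must include "intercept"
    survival: dict[str, SurvivalModel]
    eot: dict[str, EndOfTreatmentModel]
    censoring: CensoringModel
    cost_components: list[CostComponentModel]
    horizon_days: int = HORIZON_DAYS
    interval_days: int = INTERVAL_DAYS
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate covariate names")
        for c in self.covariates:
            c.validate()
        if "intercept" not in self.assignment_coefs:
            raise ConfigError("assignment_coefs must include 'intercept'")
        for arm in (ARM_FOCAL, ARM_COMPARATOR):
            if arm not in self.survival:
                raise ConfigError(f"survival model missing for arm {arm!r}")
            self.survival[arm].validate(arm)
            if arm not in self.eot:
                raise ConfigError(f"eot model missing for arm {arm!r}")
            self.eot[arm].validate(arm)
        self.censoring.validate()
        comp_names = [c.name for c in self.cost_components]
        if len(set(comp_names)) != len(comp_names):
            raise ConfigError("duplicate cost component names")
        for c in self.cost_components:
            c.validate()

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.cost_components)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _linear_predictor(
    x: pd.DataFrame, coefs: dict[str, float], centers: dict[str, float] | None = None
) -> np.ndarray:
    """Sum coef_j * (x_j - center_j); keys 'name' (numeric) or 'name=level'."""
    centers = centers or {}
    lp = np.zeros(len(x))
    for key, coef in coefs.items():
        if key == "intercept":
            lp += coef
            continue
        if "=" in key:
            name, level = key.split("=", 1)
            if name not in x.columns:
                raise ConfigError(f"coefficient references unknown covariate {name!r}")
            v = (x[name].astype(str) == level).astype(float).to_numpy()
        else:
            if key not in x.columns:
                raise ConfigError(f"coefficient references unknown covariate {key!r}")
            v = x[key].to_numpy(dtype=float)
        lp += coef * (v - centers.get(key, 0.0))
    return lp


def _draw_survival_days(
    config: SimulationConfig, x: pd.DataFrame, focal: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Continuous survival time in days by inverse transform, per arm."""
    t = np.empty(len(x))
    for arm, mask in ((ARM_FOCAL, focal), (ARM_COMPARATOR, ~focal)):
        m = config.survival[arm]
        lp = _linear_predictor(x.loc[mask], m.log_scale_coefs, m.centers)
        scale_i = m.scale * np.exp(lp)
        t[mask] = scale_i * (-np.log(u[mask])) ** (1.0 / m.shape)
    return t


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> CohortTable:
    """Generate one cohort; byte-identical output for identical config + seed."""
    config.validate()
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    (ss_cov, ss_assign, ss_surv, ss_eot, ss_cens, ss_cost, ss_epi) = root.spawn(7)
    n = config.n_patients
    h = config.horizon_days
    length = config.interval_days

    rng = np.random.default_rng(ss_cov)
    x = pd.DataFrame({c.name: c.draw(rng, n) for c in config.covariates})

    lp = _linear_predictor(x, config.assignment_coefs)
    p_focal = 1.0 / (1.0 + np.exp(-lp))
    focal = np.random.default_rng(ss_assign).random(n) < p_focal

    u = np.random.default_rng(ss_surv).random(n)
    t_cont = _draw_survival_days(config, x, focal, u)
    death_true = np.maximum(np.ceil(t_cont), 1.0)

    rng_eot = np.random.default_rng(ss_eot)
    frac = np.empty(n)
    for arm, mask in ((ARM_FOCAL, focal), (ARM_COMPARATOR, ~focal)):
        m = config.eot[arm]
        frac[mask] = rng_eot.uniform(m.frac_low, m.frac_high, int(mask.sum()))
    eot_true = np.floor(frac * death_true)

    rng_cens = np.random.default_rng(ss_cens)
    if config.censoring.rate_per_day > 0:
        c_rand = np.ceil(
            rng_cens.exponential(1.0 / config.censoring.rate_per_day, n)
        )
    else:
        c_rand = np.full(n, np.inf)
    c_day = np.minimum(c_rand, float(config.censoring.admin_cutoff_day))
    c_day = np.maximum(c_day, 1.0)
    died = death_true <= c_day
    observed_end = np.where(died, death_true, c_day)
    eot_day = np.minimum(eot_true, observed_end)

    # epidemiological / eligibility columns not already covariates
    rng_epi = np.random.default_rng(ss_epi)
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "arm": np.where(focal, ARM_FOCAL, ARM_COMPARATOR),
            "death_day": np.where(died, observed_end, np.nan),
            "censor_day": np.where(died, np.nan, observed_end),
            "eot_day": eot_day,
        }
    )
    for col in x.columns:
        patients[col] = x[col]
    if "diagnosis_to_index_days" not in patients.columns:
        patients["diagnosis_to_index_days"] = np.round(
            rng_epi.exponential(120.0, n)
        )
    if "resident_flag" not in patients.columns:
        patients["resident_flag"] = 1.0
    if "income_quintile" not in patients.columns:
        patients["income_quintile"] = rng_epi.integers(1, 6, n).astype(float)
    if "rurality" not in patients.columns:
        patients["rurality"] = (rng_epi.random(n) < 0.12).astype(float)
    if "extent_of_disease" not in patients.columns:
        if "metastatic" in x.columns:
            source = x["metastatic"].to_numpy(dtype=float) == 1.0
        else:
            source = rng_epi.random(n) < 0.69
        patients["extent_of_disease"] = np.where(
            source, "metastatic", "locally_advanced"
        )
    if "ecog" not in patients.columns:
        if "ecog1" in x.columns:
            patients["ecog"] = x["ecog1"].astype(float)
        else:
            patients["ecog"] = (rng_epi.random(n) < 0.69).astype(float)

    costs = _generate_costs(
        config, focal, observed_end, died, eot_day,
        patients["patient_id"].to_numpy(), np.random.default_rng(ss_cost),
    )
    return CohortTable(
        patients, costs, horizon_days=h,
        component_names=config.component_names,
    )


def _interval_exposure(
    observed_end: np.ndarray,
    eot_day: np.ndarray,
    horizon_days: int,
    interval_days: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed days, on-treatment days and interval lengths, per (i, k)."""
    k = -(-horizon_days // interval_days)
    starts = (np.arange(k) * interval_days)[None, :].astype(float)
    ends = np.minimum(starts + interval_days, horizon_days)
    end = np.asarray(observed_end, dtype=float)[:, None]
    obs_days = np.clip(np.minimum(end, ends) - starts, 0.0, ends - starts)
    on_days = np.clip(np.asarray(eot_day, dtype=float)[:, None] - starts, 0.0, obs_days)
    return obs_days, on_days, (ends - starts)


def _expected_interval_cost(
    comp: CostComponentModel,
    arm: str,
    obs_days: np.ndarray,
    on_days: np.ndarray,
    death_interval: np.ndarray,
    interval_days: int,
) -> np.ndarray:
    """Expected accrual per (i, k): day-rates times exposure, terminal scaled."""
    rate_on = comp.mean_on(arm) / interval_days
    rate_off = comp.mean_off(arm) / interval_days
    mean = on_days * rate_on + (obs_days - on_days) * rate_off
    return np.where(death_interval, mean * comp.terminal_mult, mean)


def _generate_costs(
    config: SimulationConfig,
    focal: np.ndarray,
    observed_end: np.ndarray,
    died: np.ndarray,
    eot_day: np.ndarray,
    patient_ids: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(focal)
    obs_days, on_days, _ = _interval_exposure(
        observed_end, eot_day, config.horizon_days, config.interval_days
    )
    k = obs_days.shape[1]
    starts = (np.arange(k) * config.interval_days)[None, :].astype(float)
    ends = np.minimum(starts + config.interval_days, config.horizon_days)
    death_col = np.asarray(observed_end, dtype=float)[:, None]
    death_interval = (
        np.asarray(died, dtype=bool)[:, None]
        & (death_col > starts)
        & (death_col <= ends)
    )

    frames = []
    for comp in config.cost_components:
        mean = np.zeros((n, k))
        for arm, mask in ((ARM_FOCAL, focal), (ARM_COMPARATOR, ~focal)):
            mean[mask] = _expected_interval_cost(
                comp, arm, obs_days[mask], on_days[mask],
                death_interval[mask], config.interval_days,
            )
        occur = rng.random((n, k)) < comp.occur_p
        z = rng.standard_normal((n, k))
        s = comp.sigma_log
        amount = np.where(
            occur & (mean > 0),
            (mean / comp.occur_p) * np.exp(s * z - 0.5 * s * s),
            0.0,
        )
        rows, cols = np.nonzero(amount)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids[rows],
                    "interval_index": cols,
                    "component": comp.name,
                    "amount": np.round(amount[rows, cols], 2),
                }
            )
        )
    costs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["patient_id", "interval_index", "component", "amount"]
    )
    return costs.sort_values(
        ["patient_id", "interval_index", "component"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """True estimands under a configuration; never computed by the pipeline."""

    true_rmst_per_arm: dict[str, float]  # undiscounted years within horizon
    true_rmst_disc_per_arm: dict[str, float]  # discounted years
    true_mean_cost_per_arm: dict[str, float]  # discounted currency
    true_incremental_rmst: float  # discounted, focal - comparator
    true_incremental_cost: float
    discount_rate: float
    survival_method: str  # "analytic" | "monte_carlo"
    mc_n: int

    def to_dict(self) -> dict:
        return asdict(self)


def weibull_rmst_days(
    shape: float, scale: float, horizon_days: float, rate: float = 0.0
) -> float:
    """Restricted mean survival in days, int_0^H S(t) disc(t) dt, by quadrature."""

    def integrand(t: float) -> float:
        s = math.exp(-((t / scale) ** shape))
        if rate:
            s *= (1.0 + rate) ** (-t / DAYS_PER_YEAR)
        return s

    val, _ = integrate.quad(integrand, 0.0, horizon_days, limit=200)
    return val


def _discounted_years_alive(tau_days: np.ndarray, rate: float) -> np.ndarray:
    """int_0^tau (1+r)^(-t/365.25) dt / 365.25, closed form per subject."""
    tau_y = tau_days / DAYS_PER_YEAR
    if rate == 0.0:
        return tau_y
    log1r = math.log1p(rate)
    return (1.0 - (1.0 + rate) ** (-tau_y)) / log1r


def compute_truth(
    config: SimulationConfig,
    rate: float = 0.015,
    mc_n: int = 200_000,
    seed: int | None = None,
) -> SimulationTruth:
    """True restricted means and mean discounted costs per counterfactual arm.

    Survival truths are analytic Weibull integrals when no covariate enters
    the survival model, otherwise Monte-Carlo averages of the conditional
    draws at ``mc_n`` subjects. Cost truths always use the Monte-Carlo
    oracle with censoring disabled and expected (noise-free) per-interval
    accrual. Common random numbers are shared across the two counterfactual
    arms, so identical arm parameters give exactly zero incrementals.
    """
    config.validate()
    analytic = not any(
        config.survival[a].log_scale_coefs for a in (ARM_FOCAL, ARM_COMPARATOR)
    )
    root = np.random.SeedSequence(
        [seed if seed is not None else config.seed, 0x7A57]
    )
    ss_cov, ss_u, ss_frac = root.spawn(3)
    h = float(config.horizon_days)

    rmst: dict[str, float] = {}
    rmst_disc: dict[str, float] = {}
    mean_cost: dict[str, float] = {}

    rng_cov = np.random.default_rng(ss_cov)
    x = pd.DataFrame({c.name: c.draw(rng_cov, mc_n) for c in config.covariates})
    u = np.random.default_rng(ss_u).random(mc_n)
    frac_u = np.random.default_rng(ss_frac).random(mc_n)

    for arm in (ARM_FOCAL, ARM_COMPARATOR):
        m = config.survival[arm]
        if analytic:
            rmst[arm] = weibull_rmst_days(m.shape, m.scale, h) / DAYS_PER_YEAR
            rmst_disc[arm] = (
                weibull_rmst_days(m.shape, m.scale, h, rate) / DAYS_PER_YEAR
            )
        lp = _linear_predictor(x, m.log_scale_coefs, m.centers)
        scale_i = m.scale * np.exp(lp)
        t_cont = scale_i * (-np.log(u)) ** (1.0 / m.shape)
        if not analytic:
            tau = np.minimum(t_cont, h)
            rmst[arm] = float(np.mean(tau)) / DAYS_PER_YEAR
            rmst_disc[arm] = float(np.mean(_discounted_years_alive(tau, rate)))

        # cost oracle mirrors the generator's integer-day discretisation
        death_days = np.maximum(np.ceil(t_cont), 1.0)
        em = config.eot[arm]
        eot_days = np.floor(
            (em.frac_low + (em.frac_high - em.frac_low) * frac_u) * death_days
        )
        mean_cost[arm] = _expected_mean_cost(config, arm, death_days, eot_days, rate)

    return SimulationTruth(
        true_rmst_per_arm=rmst,
        true_rmst_disc_per_arm=rmst_disc,
        true_mean_cost_per_arm=mean_cost,
        true_incremental_rmst=rmst_disc[ARM_FOCAL] - rmst_disc[ARM_COMPARATOR],
        true_incremental_cost=mean_cost[ARM_FOCAL] - mean_cost[ARM_COMPARATOR],
        discount_rate=rate,
        survival_method="analytic" if analytic else "monte_carlo",
        mc_n=mc_n,
    )


def _expected_mean_cost(
    config: SimulationConfig,
    arm: str,
    death_days: np.ndarray,
    eot_days: np.ndarray,
    rate: float,
    chunk: int = 50_000,
) -> float:
    """Mean of sum_k D_k E[cost_ik] over subjects, censoring disabled."""
    h, length = config.horizon_days, config.interval_days
    k = -(-h // length)
    starts = (np.arange(k) * length).astype(float)
    ends = np.minimum(starts + length, h)
    mids = (starts + ends) / 2.0
    d_k = (1.0 + rate) ** (-mids / DAYS_PER_YEAR)

    total = 0.0
    n = len(death_days)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        dd = death_days[lo:hi][:, None]
        obs = np.clip(np.minimum(dd, ends[None, :]) - starts[None, :], 0.0, None)
        on = np.clip(eot_days[lo:hi][:, None] - starts[None, :], 0.0, obs)
        death_int = (dd > starts[None, :]) & (dd <= ends[None, :])
        block = np.zeros_like(obs)
        for comp in config.cost_components:
            block += _expected_interval_cost(
                comp, arm, obs, on, death_int, length
            )
        total += float((block * d_k[None, :]).sum())
    return total / n


# ---------------------------------------------------------------------------
# presets and (de)serialisation
# ---------------------------------------------------------------------------

def default_study_config(
    n_patients: int = 1988, seed: int = 0, confounded: bool = True
) -> SimulationConfig:
    """Cohort emulating the structure of the motivating Ontario study.

    Two first-line chemotherapy strategies for advanced pancreatic cancer:
    the focal arm (gemcitabine + nab-paclitaxel-like) skews older and
    frailer, with shorter survival (median roughly 6 vs 10 months) but
    higher drug-acquisition cost; censoring is light because the disease is
    rapidly fatal relative to follow-up. Cost magnitudes are order-of-
    magnitude only.
    """
    covariates = [
        Covariate("age", "continuous", {"mean": 65.0, "sd": 9.0}),
        Covariate("female", "binary", {"p": 0.435}),
        Covariate("ecog1", "binary", {"p": 0.69}),
        Covariate("metastatic", "binary", {"p": 0.69}),
        Covariate("prior_cancer", "binary", {"p": 0.16}),
    ]
    if confounded:
        assignment = {
            "intercept": -6.83,
            "age": 0.09,
            "ecog1": 0.7,
            "metastatic": 0.5,
        }
        aft = {"age": -0.012, "ecog1": -0.25, "metastatic": -0.35}
        centers = {"age": 65.0, "ecog1": 0.69, "metastatic": 0.69}
    else:
        assignment = {"intercept": -0.13}
        aft, centers = {}, {}
    survival = {
        ARM_FOCAL: SurvivalModel(1.1, 265.0, dict(aft), dict(centers)),
        ARM_COMPARATOR: SurvivalModel(1.1, 420.0, dict(aft), dict(centers)),
    }
    eot = {
        ARM_FOCAL: EndOfTreatmentModel(0.2, 0.8),
        ARM_COMPARATOR: EndOfTreatmentModel(0.2, 0.8),
    }
    censoring = CensoringModel(rate_per_day=4e-4, admin_cutoff_day=HORIZON_DAYS)
    comps = default_cost_components()
    return SimulationConfig(
        n_patients=n_patients,
        covariates=covariates,
        assignment_coefs=assignment,
        survival=survival,
        eot=eot,
        censoring=censoring,
        cost_components=comps,
        seed=seed,
    )


def default_cost_components() -> list[CostComponentModel]:
    """Nine components with order-of-magnitude means per 30-day interval."""
    c = CostComponentModel
    return [
        c("systemic_therapy_drug_acquisition",
          mean_on_focal=3170, mean_on_comparator=540, sigma_log=0.5),
        c("acute_inpatient_hospitalization",
          mean_on_focal=1360, mean_on_comparator=1110,
          mean_off_focal=1360, mean_off_comparator=1110,
          sigma_log=1.0, terminal_mult=8.0, occur_p=0.25),
        c("physician_services",
          mean_on_focal=1140, mean_on_comparator=835,
          mean_off_focal=1140, mean_off_comparator=835,
          sigma_log=0.6, terminal_mult=2.0),
        c("ambulatory_cancer_care",
          mean_on_focal=7000, mean_on_comparator=4200,
          mean_off_focal=2300, mean_off_comparator=1100, sigma_log=0.6),
        c("emergency_department_visits",
          mean_on_focal=145, mean_on_comparator=110,
          mean_off_focal=145, mean_off_comparator=110,
          sigma_log=0.8, terminal_mult=3.0, occur_p=0.2),
        c("hospital_outpatient_clinic",
          mean_on_focal=600, mean_on_comparator=465,
          mean_off_focal=600, mean_off_comparator=465, sigma_log=0.7),
        c("outpatient_oral_drug_acquisition",
          mean_on_focal=575, mean_on_comparator=630,
          mean_off_focal=575, mean_off_comparator=630, sigma_log=0.8),
        c("home_care_services",
          mean_on_focal=735, mean_on_comparator=680,
          mean_off_focal=735, mean_off_comparator=680,
          sigma_log=0.9, terminal_mult=4.0, occur_p=0.5),
        c("other",
          mean_on_focal=290, mean_on_comparator=240,
          mean_off_focal=290, mean_off_comparator=240, sigma_log=0.8),
    ]


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain (YAML/JSON) mapping.

    A mapping with ``preset: study`` starts from :func:`default_study_config`
    and applies top-level overrides (n_patients, seed, censoring fields).
    Otherwise the mapping must spell out every section.
    """
    d = dict(d)
    if d.get("preset") == "study":
        cfg = default_study_config(
            n_patients=int(d.get("n_patients", 1988)),
            seed=int(d.get("seed", 0)),
            confounded=bool(d.get("confounded", True)),
        )
        cens = d.get("censoring", {})
        if "rate_per_day" in cens:
            cfg.censoring.rate_per_day = float(cens["rate_per_day"])
        if "admin_cutoff_day" in cens:
            cfg.censoring.admin_cutoff_day = int(cens["admin_cutoff_day"])
        cfg.validate()
        return cfg
    try:
        cfg = SimulationConfig(
            n_patients=int(d["n_patients"]),
            covariates=[Covariate(**c) for c in d["covariates"]],
            assignment_coefs={k: float(v) for k, v in d["assignment_coefs"].items()},
            survival={a: SurvivalModel(**m) for a, m in d["survival"].items()},
            eot={a: EndOfTreatmentModel(**m) for a, m in d.get("eot", {}).items()}
            or {a: EndOfTreatmentModel() for a in (ARM_FOCAL, ARM_COMPARATOR)},
            censoring=CensoringModel(**d.get("censoring", {})),
            cost_components=[CostComponentModel(**c) for c in d["cost_components"]],
            horizon_days=int(d.get("horizon_days", HORIZON_DAYS)),
            interval_days=int(d.get("interval_days", INTERVAL_DAYS)),
            seed=int(d.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"simulation config missing section {exc.args[0]!r}")
    cfg.validate()
    return cfg
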