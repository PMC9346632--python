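"""Propensity scores, stabilized IPTW, 1:1 caliper matching, balance checks.

The propensity score e(X) = P(arm = focal | X) is a maximum-likelihood
logistic regression on the baseline covariates. Stabilized inverse
probability of treatment weights are

    w_i = p_T / e_i            (focal arm)
    w_i = (1 - p_T) / (1 - e_i)  (comparator arm)

with p_T the observed treated fraction, so weights average ~1 per arm and
the weighted ("effective") arm sizes stay close to the raw ones. Balance is
judged by absolute weighted standardized differences, with |d| <= 0.1 the
conventional threshold. The matched alternative pairs patients 1:1 on the
logit of the score within a caliper of 0.2 SD of that logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import ARM_COMPARATOR, ARM_FOCAL, CohortTable
from .errors import ConfigError, ConvergenceError, SeparationError

BALANCE_THRESHOLD = 0.1
_MAX_ABS_COEF = 30.0  # |log-odds| beyond this flags separation


def design_matrix(patients: pd.DataFrame, covariate_names: list[str]) -> pd.DataFrame:
    """Expand covariates into a numeric design (categoricals -> indicator contrasts).

    Numeric columns enter as-is; string/categorical columns are expanded to
    dummies with the first level (alphabetical) as reference.
    """
    cols = []
    for name in covariate_names:
        if name not in patients.columns:
            raise ConfigError(f"covariate {name!r} not in patients table")
        col = patients[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float).rename(name))
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.extend(dummies[c] for c in dummies.columns)
    x = pd.concat(cols, axis=1)
    const = [c for c in x.columns if x[c].nunique() <= 1]
    if const:
        raise ConfigError(f"covariate(s) constant over the cohort: {const}")
    return x


@dataclass
class PropensityResult:
    """Fitted propensity model: coefficients, per-patient scores, margins."""

    coefficients: pd.Series  # intercept ("const") + per-column log-odds
    scores: np.ndarray  # e_i in (0, 1)
    focal: np.ndarray  # boolean arm indicator
    treated_fraction: float
    bse: pd.Series | None = None
    n_iterations: int | None = None


def fit_propensity(
    cohort_or_patients: CohortTable | pd.DataFrame,
    covariate_names: list[str],
    focal: np.ndarray | None = None,
) -> PropensityResult:
    """Maximum-likelihood logistic propensity fit.

    Accepts either a CohortTable or a raw patients frame plus an explicit
    focal-arm indicator (used when refitting inside bootstrap replicates).
    """
    if isinstance(cohort_or_patients, CohortTable):
        patients = cohort_or_patients.patients
        focal = cohort_or_patients.focal
    else:
        patients = cohort_or_patients
        if focal is None:
            focal = (patients["arm"] == ARM_FOCAL).to_numpy()
    x = design_matrix(patients, covariate_names)
    return fit_propensity_design(x.to_numpy(), focal, list(x.columns))


def fit_propensity_design(
    x: np.ndarray, focal: np.ndarray, column_names: list[str] | None = None
) -> PropensityResult:
    """Logistic fit on an already-expanded numeric design matrix."""
    focal = np.asarray(focal, dtype=bool)
    if focal.sum() < 2 or (~focal).sum() < 2:
        raise ConfigError("need at least 2 patients per arm")
    xc = sm.add_constant(np.asarray(x, dtype=float), has_constant="add")
    names = ["const"] + (
        column_names if column_names is not None else [f"x{j}" for j in range(x.shape[1])]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation re-checked below
        try:
            res = sm.Logit(focal.astype(float), xc).fit(
                method="newton", maxiter=100, tol=1e-10, disp=0,
                warn_convergence=False,
            )
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(
                "perfect separation detected in the propensity model; "
                "remove the offending covariate"
            ) from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > _MAX_ABS_COEF:
        raise SeparationError(
            "propensity coefficients diverged (perfect or quasi-separation); "
            "remove the offending covariate"
        )
    n_iter = int(res.mle_retvals.get("iterations", 0))
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"propensity model did not converge in {n_iter} iterations"
        )
    scores = np.asarray(res.predict(xc), dtype=float)
    scores = np.clip(scores, 1e-12, 1 - 1e-12)
    return PropensityResult(
        coefficients=pd.Series(params, index=names),
        scores=scores,
        focal=focal,
        treated_fraction=float(focal.mean()),
        bse=pd.Series(np.asarray(res.bse, dtype=float), index=names),
        n_iterations=n_iter,
    )


@dataclass
class WeightedCohort:
    """Per-patient analysis weights under a weighting or matching scheme."""

    weights: np.ndarray
    focal: np.ndarray
    scheme: str  # "iptw_stabilized" | "psm_indicator"
    pairs: list[tuple[int, int]] | None = None  # (focal_idx, comparator_idx)

    @property
    def effective_sizes(self) -> dict[str, float]:
        return {
            ARM_FOCAL: float(self.weights[self.focal].sum()),
            ARM_COMPARATOR: float(self.weights[~self.focal].sum()),
        }


def stabilized_weights(
    ps: PropensityResult, trim: tuple[float, float] | None = None
) -> WeightedCohort:
    """Stabilized IPTW weights from a fitted propensity model.

    ``trim``, if given, clips scores to [lo, hi] before weighting (off by
    default; no trimming is applied in the base analysis).
    """
    e = ps.scores
    if trim is not None:
        e = np.clip(e, trim[0], trim[1])
    p_t = ps.treated_fraction
    w = np.where(ps.focal, p_t / e, (1.0 - p_t) / (1.0 - e))
    return WeightedCohort(weights=w, focal=ps.focal, scheme="iptw_stabilized")


def unit_weights(focal: np.ndarray) -> WeightedCohort:
    """Unweighted ("crude") analysis expressed in the same container."""
    focal = np.asarray(focal, dtype=bool)
    return WeightedCohort(
        weights=np.ones(len(focal)), focal=focal, scheme="unweighted"
    )


def standardized_difference(
    x_focal: np.ndarray,
    x_comparator: np.ndarray,
    w_focal: np.ndarray | None = None,
    w_comparator: np.ndarray | None = None,
    kind: str = "continuous",
) -> float:
    """Absolute (weighted) standardized difference between two samples.

    continuous: |m1 - m2| / sqrt((s1^2 + s2^2) / 2) with weighted means and
    frequency-weight variances sum(w (x - m)^2) / (sum(w) - 1);
    binary: |p1 - p2| / sqrt((p1 (1 - p1) + p2 (1 - p2)) / 2) with weighted
    prevalences. Zero pooled variance with a nonzero mean difference is
    reported as inf with a warning.
    """
    x1 = np.asarray(x_focal, dtype=float)
    x2 = np.asarray(x_comparator, dtype=float)
    w1 = np.ones_like(x1) if w_focal is None else np.asarray(w_focal, dtype=float)
    w2 = np.ones_like(x2) if w_comparator is None else np.asarray(w_comparator, dtype=float)
    if w1.sum() <= 0 or w2.sum() <= 0:
        raise ValueError("nonzero total weight required in each arm")
    m1 = np.sum(w1 * x1) / np.sum(w1)
    m2 = np.sum(w2 * x2) / np.sum(w2)
    if kind == "binary":
        pooled = (m1 * (1 - m1) + m2 * (1 - m2)) / 2.0
    elif kind == "continuous":
        v1 = np.sum(w1 * (x1 - m1) ** 2) / (np.sum(w1) - 1.0)
        v2 = np.sum(w2 * (x2 - m2) ** 2) / (np.sum(w2) - 1.0)
        pooled = (v1 + v2) / 2.0
    else:
        raise ValueError(f"kind must be 'continuous' or 'binary', got {kind!r}")
    diff = abs(m1 - m2)
    if pooled <= 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled variance with nonzero mean difference")
        return float("inf")
    return float(diff / np.sqrt(pooled))


def standardized_difference_from_counts(
    count_focal: float, n_focal: float, count_comparator: float, n_comparator: float
) -> float:
    """Binary standardized difference from (possibly weighted) counts and sizes."""
    p1 = count_focal / n_focal
    p2 = count_comparator / n_comparator
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    return float(abs(p1 - p2) / np.sqrt(pooled))


def balance_table(
    cohort: CohortTable,
    covariate_names: list[str],
    weighted: WeightedCohort,
) -> pd.DataFrame:
    """Per-covariate |standardized difference| before and after weighting.

    Categorical covariates are expanded to one binary row per level.
    Matched cohorts (0/1 weights) restrict to matched patients.
    """
    p = cohort.patients
    focal = weighted.focal
    rows = []
    for name in covariate_names:
        col = p[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            items = [(name, col.astype(float).to_numpy(), "continuous")]
        elif pd.api.types.is_numeric_dtype(col):
            items = [(name, col.astype(float).to_numpy(), "binary")]
        else:
            items = [
                (f"{name}={lvl}", (col == lvl).astype(float).to_numpy(), "binary")
                for lvl in sorted(col.dropna().unique())
            ]
        for label, x, kind in items:
            d_before = standardized_difference(
                x[focal], x[~focal], kind=kind
            )
            d_after = standardized_difference(
                x[focal], x[~focal],
                weighted.weights[focal], weighted.weights[~focal],
                kind=kind,
            )
            rows.append(
                {
                    "covariate": label,
                    "kind": kind,
                    "d_unweighted": d_before,
                    "d_weighted": d_after,
                    "balanced": abs(d_after) <= BALANCE_THRESHOLD,
                }
            )
    return pd.DataFrame(rows)


def psm_match(
    ps: PropensityResult,
    caliper_sd: float = 0.2,
    seed: int = 0,
    caliper_logit: float | None = None,
) -> WeightedCohort:
    """Greedy 1:1 nearest-neighbour matching without replacement on logit(e).

    The caliper is ``caliper_sd`` times the SD of logit(e) over the whole
    cohort (or an absolute logit-scale width via ``caliper_logit``). Focal
    patients are processed in seed-randomized order; each takes the nearest
    still-available comparator within the caliper. Matched patients receive
    weight 1, all others 0.
    """
    focal = ps.focal
    if focal.sum() == 0 or (~focal).sum() == 0:
        raise ConfigError("both arms must be nonempty for matching")
    logit = np.log(ps.scores / (1.0 - ps.scores))
    if caliper_logit is None:
        caliper_logit = caliper_sd * float(np.std(logit, ddof=1))
    rng = np.random.default_rng(seed)

    f_idx = np.flatnonzero(focal)
    c_idx = np.flatnonzero(~focal)
    order = rng.permutation(len(f_idx))
    avail = np.ones(len(c_idx), dtype=bool)
    c_logit = logit[c_idx]
    pairs: list[tuple[int, int]] = []
    for fi in f_idx[order]:
        if not avail.any():
            break
        dist = np.abs(c_logit - logit[fi])
        dist[~avail] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= caliper_logit:
            pairs.append((int(fi), int(c_idx[j])))
            avail[j] = False
    if not pairs:
        warnings.warn("no pairs within caliper; matched cohort is empty")
    w = np.zeros(len(focal))
    for fi, ci in pairs:
        w[fi] = 1.0
        w[ci] = 1.0
    return WeightedCohort(weights=w, focal=focal, scheme="psm_indicator", pairs=pairs)
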