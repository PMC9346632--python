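"""Incremental economics: ICER with dominance, net-benefit regression,
nonparametric bootstrap, cost-effectiveness plane and acceptability curve.

The incremental cost-effectiveness ratio is dC/dE (focal minus comparator).
When the focal strategy is both more costly and less effective it is
*dominated* (no meaningful ratio); more effective and cheaper, it is
*dominant*. At a willingness-to-pay threshold lambda, each patient's net
monetary benefit is NMB_i = lambda * E_i - C_i; weighted least squares of
NMB on the treatment indicator gives the incremental net monetary benefit
INMB(lambda) = lambda * dE - dC as the treatment coefficient. Uncertainty
comes from resampling patients with replacement and re-estimating the whole
pipeline (propensity model, weights, censoring survivor, IPCW) inside each
replicate; the acceptability curve CEAC(lambda) is the fraction of
replicates with positive INMB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError


def default_wtp_grid(stop: float = 200_000.0, step: float = 10_000.0) -> np.ndarray:
    """Willingness-to-pay grid: 0 to `stop` in `step` increments."""
    return np.arange(0.0, stop + step / 2, step)


@dataclass
class ICERResult:
    """Point ICER or a dominance status when the ratio is not meaningful."""

    status: str  # "dominated" | "dominant" | "quadrant_I" | "quadrant_III" | ...
    ratio: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ratio is None:
            return self.status
        return f"{self.ratio:,.0f} per unit ({self.status})"


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Classify (dC, dE) into a ratio with quadrant label or a dominance status."""
    if delta_effect == 0:
        if delta_cost > 0:
            return ICERResult(status="more_costly_equal_effect")
        if delta_cost < 0:
            return ICERResult(status="cost_saving_equal_effect")
        return ICERResult(status="equivalent")
    if delta_cost > 0 and delta_effect < 0:
        return ICERResult(status="dominated")
    if delta_cost < 0 and delta_effect > 0:
        return ICERResult(status="dominant")
    quadrant = "quadrant_I" if delta_effect > 0 else "quadrant_III"
    return ICERResult(status=quadrant, ratio=float(delta_cost / delta_effect))


def patient_nmb(
    effect: np.ndarray, cost: np.ndarray, wtp: float
) -> np.ndarray:
    """Per-patient net monetary benefit lambda * E_i - C_i."""
    return wtp * np.asarray(effect, dtype=float) - np.asarray(cost, dtype=float)


def net_benefit_regression(
    effect: np.ndarray,
    cost: np.ndarray,
    focal: np.ndarray,
    weights: np.ndarray,
    wtp_grid: np.ndarray,
) -> pd.DataFrame:
    """Weighted least squares of NMB_i on the treatment indicator, per lambda.

    The treatment coefficient equals the difference of weighted arm means of
    NMB, i.e. INMB(lambda) = lambda * dE - dC.
    """
    focal = np.asarray(focal, dtype=bool)
    w = np.asarray(weights, dtype=float)
    if w[focal].sum() <= 0 or w[~focal].sum() <= 0:
        raise ConfigError("both arms need positive total weight")
    x = sm.add_constant(focal.astype(float))
    rows = []
    for lam in np.asarray(wtp_grid, dtype=float):
        nmb = patient_nmb(effect, cost, lam)
        fit = sm.WLS(nmb, x, weights=w).fit()
        rows.append({"wtp": lam, "inmb": float(fit.params[1])})
    return pd.DataFrame(rows)


def quadrant_proportions(
    delta_effect: np.ndarray, delta_cost: np.ndarray
) -> dict[str, float]:
    """Share of bootstrap draws in each CE-plane quadrant.

    East/west splits on the sign of dE, north/south on the sign of dC
    (x = dE, y = dC); draws exactly on an axis count toward the
    west/south side.
    """
    de = np.asarray(delta_effect, dtype=float)
    dc = np.asarray(delta_cost, dtype=float)
    east, north = de > 0, dc > 0
    n = len(de)
    return {
        "NE": float(np.sum(east & north) / n),
        "NW": float(np.sum(~east & north) / n),
        "SW": float(np.sum(~east & ~north) / n),
        "SE": float(np.sum(east & ~north) / n),
    }


def ceac_from_draws(
    delta_effect: np.ndarray, delta_cost: np.ndarray, wtp_grid: np.ndarray
) -> pd.DataFrame:
    """CEAC(lambda) = fraction of replicates with lambda * dE - dC > 0."""
    de = np.asarray(delta_effect, dtype=float)[None, :]
    dc = np.asarray(delta_cost, dtype=float)[None, :]
    lam = np.asarray(wtp_grid, dtype=float)[:, None]
    prob = np.mean(lam * de - dc > 0, axis=1)
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})


@dataclass
class CEResult:
    """Point estimates plus bootstrap inference for one effectiveness measure."""

    effect_label: str  # "ly" | "qaly"
    delta_effect: float
    delta_cost: float
    icer: ICERResult
    inmb_grid: pd.DataFrame  # wtp, inmb, ci_low, ci_high
    draws: pd.DataFrame  # replicate, delta_effect, delta_cost
    ci_delta_effect: tuple[float, float]
    ci_delta_cost: tuple[float, float]
    quadrants: dict[str, float]
    ceac: pd.DataFrame  # wtp, probability
    n_single_arm_redraws: int = 0


def bootstrap_deltas(
    estimator: Callable[[np.ndarray], tuple],
    n: int,
    focal: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Resample patients with replacement and re-estimate deltas per replicate.

    ``estimator`` maps an index array to a tuple of deltas. Replicates whose
    resample leaves an arm empty are redrawn (counted; warned if they exceed
    1% of the requested replicates).
    """
    if n_boot < 2:
        raise ConfigError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    focal = np.asarray(focal, dtype=bool)
    draws = []
    redraws = 0
    while len(draws) < n_boot:
        idx = rng.integers(0, n, n)
        nf = int(focal[idx].sum())
        if nf < 2 or (n - nf) < 2:
            redraws += 1
            continue
        draws.append(estimator(idx))
    if redraws > 0.01 * n_boot:
        warnings.warn(
            f"{redraws} bootstrap resamples redrawn for single-arm draws "
            f"(> 1% of B={n_boot})"
        )
    return np.asarray(draws, dtype=float), redraws


def percentile_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(x, lo)),
        float(np.quantile(x, 1.0 - lo)),
    )


def evaluate_ce(
    effect_label: str,
    effect: np.ndarray,
    cost: np.ndarray,
    focal: np.ndarray,
    weights: np.ndarray,
    boot_delta_effect: np.ndarray,
    boot_delta_cost: np.ndarray,
    wtp_grid: np.ndarray | None = None,
    n_single_arm_redraws: int = 0,
) -> CEResult:
    """Assemble a CEResult from per-patient contributions and bootstrap draws."""
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    focal = np.asarray(focal, dtype=bool)
    w = np.asarray(weights, dtype=float)

    def wmean_diff(v: np.ndarray) -> float:
        return float(
            np.sum(w[focal] * v[focal]) / np.sum(w[focal])
            - np.sum(w[~focal] * v[~focal]) / np.sum(w[~focal])
        )

    d_eff = wmean_diff(np.asarray(effect, dtype=float))
    d_cost = wmean_diff(np.asarray(cost, dtype=float))
    nbr = net_benefit_regression(effect, cost, focal, w, wtp_grid)
    lam = nbr["wtp"].to_numpy()
    boot_inmb = lam[:, None] * boot_delta_effect[None, :] - boot_delta_cost[None, :]
    nbr["ci_low"] = np.quantile(boot_inmb, 0.025, axis=1)
    nbr["ci_high"] = np.quantile(boot_inmb, 0.975, axis=1)
    draws = pd.DataFrame(
        {
            "replicate": np.arange(len(boot_delta_effect)),
            "delta_effect": boot_delta_effect,
            "delta_cost": boot_delta_cost,
        }
    )
    return CEResult(
        effect_label=effect_label,
        delta_effect=d_eff,
        delta_cost=d_cost,
        icer=icer(d_cost, d_eff),
        inmb_grid=nbr,
        draws=draws,
        ci_delta_effect=percentile_ci(boot_delta_effect),
        ci_delta_cost=percentile_ci(boot_delta_cost),
        quadrants=quadrant_proportions(boot_delta_effect, boot_delta_cost),
        ceac=ceac_from_draws(boot_delta_effect, boot_delta_cost, wtp_grid),
        n_single_arm_redraws=n_single_arm_redraws,
    )
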