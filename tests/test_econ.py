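"""ICER/dominance, net-benefit regression, bootstrap, CE plane, CEAC."""

import numpy as np
import pandas as pd
import pytest

from rwcea.cohort import ARM_COMPARATOR, ARM_FOCAL
from rwcea.econ import (
    bootstrap_deltas,
    ceac_from_draws,
    default_wtp_grid,
    icer,
    net_benefit_regression,
    patient_nmb,
    quadrant_proportions,
)
from rwcea.errors import ConfigError
from rwcea.pipeline import AnalysisSpec, run_ce
from rwcea.synthetic import default_study_config, generate_cohort

COVS = ["age", "female", "ecog1", "metastatic", "prior_cancer"]


class TestICER:
    @pytest.mark.parametrize(
        "dc,de,status,ratio",
        [
            (2366.0, -0.28, "dominated", None),
            (-100.0, 0.5, "dominant", None),
            (1000.0, 0.5, "quadrant_I", 2000.0),
            (-1000.0, -0.5, "quadrant_III", 2000.0),
            (500.0, 0.0, "more_costly_equal_effect", None),
            (-500.0, 0.0, "cost_saving_equal_effect", None),
            (0.0, 0.0, "equivalent", None),
        ],
    )
    def test_classification(self, dc, de, status, ratio):
        r = icer(dc, de)
        assert r.status == status
        if ratio is None:
            assert r.ratio is None
        else:
            assert r.ratio == pytest.approx(ratio)


class TestNMB:
    def test_lambda_zero_is_negative_cost(self):
        c = np.array([10.0, 20.0])
        e = np.array([1.0, 2.0])
        np.testing.assert_allclose(patient_nmb(e, c, 0.0), -c)

    def test_arithmetic_at_50k(self):
        # arm-level dE = -0.28, dC = 2366 -> INMB = -16366 at lambda = 50000
        assert 50_000 * (-0.28) - 2366 == pytest.approx(-16_366)

    def test_doubling_lambda_doubles_effect_term(self):
        e, c = np.array([1.5]), np.array([100.0])
        n1 = patient_nmb(e, c, 10_000.0) + c
        n2 = patient_nmb(e, c, 20_000.0) + c
        np.testing.assert_allclose(n2, 2 * n1)


class TestNetBenefitRegression:
    def test_coefficient_equals_weighted_mean_difference(self):
        effect = np.array([1.0, 1.2, 0.9, 0.5, 0.7, 0.6])
        cost = np.array([10.0, 12.0, 9.0, 20.0, 25.0, 22.0]) * 1000
        focal = np.array([True, True, True, False, False, False])
        w = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 3.0])
        grid = np.array([0.0, 50_000.0, 100_000.0])
        out = net_benefit_regression(effect, cost, focal, w, grid)
        for lam, coef in zip(out["wtp"], out["inmb"]):
            nmb = patient_nmb(effect, cost, lam)
            m1 = np.sum(w[focal] * nmb[focal]) / np.sum(w[focal])
            m0 = np.sum(w[~focal] * nmb[~focal]) / np.sum(w[~focal])
            assert coef == pytest.approx(m1 - m0, rel=1e-12, abs=1e-9)

    def test_inmb_linear_in_lambda(self):
        effect = np.array([1.0, 0.8, 0.5, 0.4])
        cost = np.array([5.0, 6.0, 7.0, 8.0]) * 1000
        focal = np.array([True, True, False, False])
        w = np.ones(4)
        grid = default_wtp_grid()
        out = net_benefit_regression(effect, cost, focal, w, grid)
        de = effect[:2].mean() - effect[2:].mean()
        dc = cost[:2].mean() - cost[2:].mean()
        np.testing.assert_allclose(out["inmb"], grid * de - dc, atol=1e-9)

    def test_identical_nmb_gives_zero_coefficient(self):
        effect = np.array([1.0, 1.0, 1.0, 1.0])
        cost = np.array([5.0, 5.0, 5.0, 5.0])
        focal = np.array([True, True, False, False])
        out = net_benefit_regression(effect, cost, focal, np.ones(4),
                                     np.array([50_000.0]))
        assert out["inmb"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_arm_errors(self):
        with pytest.raises(ConfigError):
            net_benefit_regression(
                np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                np.array([True, True]), np.ones(2), np.array([0.0]),
            )


class TestCEACAndQuadrants:
    def test_ceac_equals_recount_of_positive_inmb_replicates(self):
        rng = np.random.default_rng(7)
        de = rng.normal(-0.2, 0.1, 500)
        dc = rng.normal(2000.0, 4000.0, 500)
        grid = default_wtp_grid()
        ceac = ceac_from_draws(de, dc, grid)
        for lam, prob in zip(ceac["wtp"], ceac["probability"]):
            recount = np.mean(lam * de - dc > 0)
            assert prob == recount

    def test_ceac_limits(self):
        rng = np.random.default_rng(11)
        de = rng.normal(0.1, 0.2, 400)
        dc = rng.normal(500.0, 1000.0, 400)
        ceac0 = ceac_from_draws(de, dc, np.array([0.0]))["probability"].iloc[0]
        assert ceac0 == np.mean(dc < 0)
        ceac_inf = ceac_from_draws(de, dc, np.array([1e12]))["probability"].iloc[0]
        assert ceac_inf == np.mean(de > 0)

    def test_quadrants_match_sign_logic(self):
        de = np.array([1.0, -1.0, -1.0, 1.0])
        dc = np.array([1.0, 1.0, -1.0, -1.0])
        q = quadrant_proportions(de, dc)
        assert q == {"NE": 0.25, "NW": 0.25, "SW": 0.25, "SE": 0.25}


class TestBootstrap:
    def test_degenerate_cohort_zero_width_ci(self):
        # identical patients duplicated: every resample produces the same
        # deltas, so percentile CIs collapse to a point
        est_calls = []

        focal = np.array([True, False] * 10)

        def estimator(idx):
            est_calls.append(idx)
            return (0.5, 1000.0)

        draws, redraws = bootstrap_deltas(estimator, 20, focal, n_boot=25, seed=3)
        assert draws.shape == (25, 2)
        assert np.ptp(draws, axis=0).tolist() == [0.0, 0.0]

    def test_reproducible_by_seed(self):
        focal = np.array([True] * 10 + [False] * 10)

        def estimator(idx):
            return (float(idx.sum()),)

        d1, _ = bootstrap_deltas(estimator, 20, focal, n_boot=10, seed=5)
        d2, _ = bootstrap_deltas(estimator, 20, focal, n_boot=10, seed=5)
        assert (d1 == d2).all()

    def test_single_arm_resamples_redrawn_with_warning(self):
        focal = np.array([True] * 2 + [False] * 18)

        def estimator(idx):
            return (0.0,)

        with pytest.warns(UserWarning, match="redrawn"):
            draws, redraws = bootstrap_deltas(
                estimator, 20, focal, n_boot=200, seed=0
            )
        assert len(draws) == 200
        assert redraws > 2


class TestEndToEndCE:
    def test_negative_inmb_everywhere_when_dominated(self):
        # cohort calibrated to dE < 0 with clearly positive dC: the focal
        # strategy is dominated and INMB stays negative across the WTP grid
        cfg = default_study_config(n_patients=1_500, seed=41)
        for comp in cfg.cost_components:
            if comp.name == "systemic_therapy_drug_acquisition":
                comp.mean_on_focal = 6_000.0
        cohort = generate_cohort(cfg, seed=41)
        spec = AnalysisSpec(covariates=COVS)
        res = run_ce(cohort, spec, n_boot=60, seed=41)
        for label in ("ly", "qaly"):
            r = res[label]
            assert r.delta_effect < 0 and r.delta_cost > 0
            assert r.icer.status == "dominated"
            assert (r.inmb_grid["inmb"] < 0).all()
        # INMB exactly linear with slope dE, intercept -dC on the grid
        g = res["ly"].inmb_grid
        np.testing.assert_allclose(
            g["inmb"],
            g["wtp"] * res["ly"].delta_effect - res["ly"].delta_cost,
            atol=1e-6,
        )

    def test_ceac_crosses_half_near_true_icer(self):
        # focal arm beneficial and more costly: the acceptability curve
        # should cross 0.5 within one grid step of the point ICER
        from rwcea.synthetic import CostComponentModel

        cfg = default_study_config(n_patients=1_200, seed=43, confounded=False)
        cfg.survival[ARM_FOCAL].scale = 520.0
        cfg.survival[ARM_COMPARATOR].scale = 420.0
        # drug acquisition is the only cost, so the cost differential (and
        # hence the ICER) is controlled and lies inside the WTP grid
        cfg.cost_components = [
            CostComponentModel(
                "systemic_therapy_drug_acquisition",
                mean_on_focal=2_000.0, mean_on_comparator=500.0, sigma_log=0.5,
            )
        ]
        cohort = generate_cohort(cfg, seed=43)
        spec = AnalysisSpec(covariates=COVS)
        step = 10_000.0
        grid = np.arange(0.0, 150_000.0 + 1, step)
        res = run_ce(cohort, spec, n_boot=500, seed=43, wtp_grid=grid)["ly"]
        assert res.delta_effect > 0 and res.delta_cost > 0
        point_icer = res.icer.ratio
        ceac = res.ceac
        crossings = np.flatnonzero(
            np.diff((ceac["probability"] >= 0.5).astype(int)) != 0
        )
        assert len(crossings) >= 1
        lam_cross = ceac["wtp"].iloc[int(crossings[0]) + 1]
        assert abs(lam_cross - point_icer) <= step

    def test_rerun_same_seed_identical(self):
        cfg = default_study_config(n_patients=400, seed=47)
        cohort = generate_cohort(cfg, seed=47)
        spec = AnalysisSpec(covariates=COVS)
        r1 = run_ce(cohort, spec, n_boot=20, seed=9)["ly"]
        r2 = run_ce(cohort, spec, n_boot=20, seed=9)["ly"]
        pd.testing.assert_frame_equal(r1.draws, r2.draws)
        assert r1.delta_cost == r2.delta_cost
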