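"""Propensity fit, stabilized IPTW, standardized differences, matching."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rwcea.cohort import ARM_COMPARATOR, ARM_FOCAL
from rwcea.errors import ConfigError, SeparationError
from rwcea.propensity import (
    balance_table,
    fit_propensity,
    fit_propensity_design,
    psm_match,
    stabilized_weights,
    standardized_difference,
    standardized_difference_from_counts,
)
from rwcea.synthetic import default_study_config, generate_cohort

from conftest import make_cohort


def cell_2x2_cohort():
    """Single binary covariate, cells X=1: 80 focal/20 comparator;
    X=0: 20 focal/80 comparator. Saturated MLE equals cell proportions."""
    rows = []
    for x, arm, count in [
        (1.0, ARM_FOCAL, 80), (1.0, ARM_COMPARATOR, 20),
        (0.0, ARM_FOCAL, 20), (0.0, ARM_COMPARATOR, 80),
    ]:
        rows += [{"arm": arm, "x": x, "death_day": 100.0, "eot_day": 50.0}] * count
    return make_cohort(rows)


class TestFit:
    def test_saturated_2x2_scores_are_cell_proportions(self):
        ps = fit_propensity(cell_2x2_cohort(), ["x"])
        x = cell_2x2_cohort().patients["x"].to_numpy()
        assert ps.scores[x == 1.0] == pytest.approx(0.8, abs=1e-6)
        assert ps.scores[x == 0.0] == pytest.approx(0.2, abs=1e-6)
        assert ps.treated_fraction == pytest.approx(0.5)

    def test_null_covariate_coefficient_within_3se(self):
        rng = np.random.default_rng(42)
        n = 10_000
        rows = [
            {"arm": ARM_FOCAL if rng.random() < 0.5 else ARM_COMPARATOR,
             "z": float(v), "death_day": 100.0}
            for v in rng.normal(size=n)
        ]
        ps = fit_propensity(make_cohort(rows), ["z"])
        assert abs(ps.coefficients["z"]) < 3 * ps.bse["z"]

    def test_perfect_separation_raises(self):
        rows = (
            [{"arm": ARM_FOCAL, "x": 1.0, "death_day": 10.0}] * 20
            + [{"arm": ARM_COMPARATOR, "x": 0.0, "death_day": 10.0}] * 20
        )
        with pytest.raises(SeparationError):
            fit_propensity(make_cohort(rows), ["x"])

    def test_constant_covariate_rejected(self):
        rows = (
            [{"arm": ARM_FOCAL, "x": 1.0, "death_day": 10.0}] * 5
            + [{"arm": ARM_COMPARATOR, "x": 1.0, "death_day": 10.0}] * 5
        )
        with pytest.raises(ConfigError, match="constant"):
            fit_propensity(make_cohort(rows), ["x"])

    def test_categorical_covariate_expanded(self):
        rng = np.random.default_rng(1)
        rows = [
            {"arm": ARM_FOCAL if rng.random() < 0.5 else ARM_COMPARATOR,
             "region": rng.choice(["a", "b", "c"]), "death_day": 10.0}
            for _ in range(300)
        ]
        ps = fit_propensity(make_cohort(rows), ["region"])
        assert {"region_b", "region_c"} <= set(ps.coefficients.index)


class TestStabilizedWeights:
    def test_hand_arithmetic_from_2x2(self):
        ps = fit_propensity(cell_2x2_cohort(), ["x"])
        wc = stabilized_weights(ps)
        x = cell_2x2_cohort().patients["x"].to_numpy()
        focal = ps.focal
        # p_T = 0.5: focal with e=0.8 -> 0.625; comparator with e=0.8 -> 2.5
        assert wc.weights[focal & (x == 1.0)] == pytest.approx(0.625, abs=1e-6)
        assert wc.weights[~focal & (x == 1.0)] == pytest.approx(2.5, abs=1e-5)
        assert wc.weights[focal & (x == 0.0)] == pytest.approx(2.5, abs=1e-5)

    def test_scores_equal_margin_give_unit_weights(self):
        rng = np.random.default_rng(0)
        rows = [
            {"arm": ARM_FOCAL if rng.random() < 0.4 else ARM_COMPARATOR,
             "death_day": 10.0}
            for _ in range(400)
        ]
        cohort = make_cohort(rows)
        from rwcea.propensity import PropensityResult

        focal = cohort.focal
        p_t = focal.mean()
        ps = PropensityResult(
            coefficients=pd.Series({"const": 0.0}),
            scores=np.full(cohort.n, p_t),
            focal=focal,
            treated_fraction=float(p_t),
        )
        wc = stabilized_weights(ps)
        assert np.allclose(wc.weights, 1.0)

    def test_effective_size_near_n_on_simulated_cohort(self):
        cfg = default_study_config(n_patients=4_000, seed=9)
        cohort = generate_cohort(cfg, seed=9)
        ps = fit_propensity(cohort, ["age", "female", "ecog1", "metastatic"])
        wc = stabilized_weights(ps)
        total = sum(wc.effective_sizes.values())
        assert abs(total - cohort.n) / cohort.n < 0.01


class TestStandardizedDifference:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert standardized_difference(x, x) == 0.0
        b = np.array([0.0, 1.0, 1.0])
        assert standardized_difference(b, b, kind="binary") == 0.0

    def test_continuous_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(0.3, 1.1, 50), rng.normal(0.0, 0.9, 60)
        w1, w2 = rng.uniform(0.5, 2.0, 50), rng.uniform(0.5, 2.0, 60)
        m1 = np.average(x1, weights=w1)
        m2 = np.average(x2, weights=w2)
        v1 = np.sum(w1 * (x1 - m1) ** 2) / (w1.sum() - 1)
        v2 = np.sum(w2 * (x2 - m2) ** 2) / (w2.sum() - 1)
        expected = abs(m1 - m2) / np.sqrt((v1 + v2) / 2)
        got = standardized_difference(x1, x2, w1, w2, kind="continuous")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_nonzero_difference_is_inf_with_warning(self):
        with pytest.warns(UserWarning):
            d = standardized_difference(
                np.array([1.0, 1.0]), np.array([0.0, 0.0]), kind="binary"
            )
        assert d == np.inf

    def test_weighted_counts_helper_symmetry(self):
        d1 = standardized_difference_from_counts(395.9, 936.55, 446.7, 1046.61)
        d2 = standardized_difference_from_counts(446.7, 1046.61, 395.9, 936.55)
        assert d1 == pytest.approx(d2)


class TestWLSIdentity:
    def test_wls_binary_regressor_equals_weighted_mean_difference(self):
        # 6-patient toy with hand-computable weighted arm means
        y = np.array([10.0, 12.0, 9.0, 20.0, 22.0, 25.0])
        arm = np.array([0, 0, 0, 1, 1, 1])
        w = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 3.0])
        m1 = np.sum(w[arm == 1] * y[arm == 1]) / np.sum(w[arm == 1])
        m0 = np.sum(w[arm == 0] * y[arm == 0]) / np.sum(w[arm == 0])
        fit = sm.WLS(y, sm.add_constant(arm.astype(float)), weights=w).fit()
        assert fit.params[1] == pytest.approx(m1 - m0, abs=1e-12)


class TestBalance:
    def test_iptw_shrinks_standardized_differences(self):
        cfg = default_study_config(n_patients=5_000, seed=13)
        cohort = generate_cohort(cfg, seed=13)
        confounders = ["age", "ecog1", "metastatic"]
        ps = fit_propensity(cohort, confounders + ["female", "prior_cancer"])
        bt = balance_table(cohort, confounders, stabilized_weights(ps))
        assert (bt["d_weighted"] < bt["d_unweighted"]).all()
        assert (bt["d_weighted"] <= 0.1).all()


class TestMatching:
    def toy_ps(self, logits_focal, logits_comparator):
        from rwcea.propensity import PropensityResult
        from scipy.special import expit

        logits = np.array(list(logits_focal) + list(logits_comparator))
        focal = np.array([True] * len(logits_focal) + [False] * len(logits_comparator))
        return PropensityResult(
            coefficients=pd.Series(dtype=float),
            scores=expit(logits),
            focal=focal,
            treated_fraction=float(focal.mean()),
        )

    def test_identical_scores_match_everyone(self):
        ps = self.toy_ps([0.0] * 3, [0.0] * 5)
        wc = psm_match(ps, seed=1, caliper_logit=0.1)
        assert len(wc.pairs) == 3
        assert wc.effective_sizes[ARM_FOCAL] == 3
        assert wc.effective_sizes[ARM_COMPARATOR] == 3

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_3v3_toy_exactly_two_pairs(self, seed):
        # logits focal {0, 1, 5}, comparator {0.1, 1.2, 9}; caliper 0.5:
        # admissible pairs only (0, 0.1) and (1, 1.2); 5 and 9 stay unmatched
        ps = self.toy_ps([0.0, 1.0, 5.0], [0.1, 1.2, 9.0])
        wc = psm_match(ps, seed=seed, caliper_logit=0.5)
        assert len(wc.pairs) == 2
        matched_logits = {round(np.log(ps.scores[i] / (1 - ps.scores[i])), 6)
                          for pair in wc.pairs for i in pair}
        assert matched_logits == {0.0, 0.1, 1.0, 1.2}

    def test_empty_arm_errors(self):
        ps = self.toy_ps([0.0, 1.0], [])
        with pytest.raises(ConfigError, match="nonempty"):
            psm_match(ps)

    def test_no_pairs_within_caliper_warns_empty(self):
        ps = self.toy_ps([-5.0], [5.0])
        with pytest.warns(UserWarning, match="no pairs"):
            wc = psm_match(ps, caliper_logit=0.5)
        assert wc.weights.sum() == 0

    def test_every_pair_within_caliper_and_balance(self):
        cfg = default_study_config(n_patients=5_000, seed=21)
        cohort = generate_cohort(cfg, seed=21)
        confounders = ["age", "ecog1", "metastatic"]
        ps = fit_propensity(cohort, confounders + ["female", "prior_cancer"])
        caliper_sd = 0.2
        wc = psm_match(ps, caliper_sd=caliper_sd, seed=3)
        logit = np.log(ps.scores / (1 - ps.scores))
        caliper = caliper_sd * np.std(logit, ddof=1)
        for fi, ci in wc.pairs:
            assert abs(logit[fi] - logit[ci]) <= caliper
        matched = wc.weights > 0
        sub = cohort.subset(matched)
        from rwcea.propensity import WeightedCohort

        bt = balance_table(
            sub, confounders,
            WeightedCohort(np.ones(sub.n), sub.focal, "psm_indicator"),
        )
        assert (bt["d_weighted"] <= 0.1).all()
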