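"""Scenario projection, GCM averaging, correlations and threshold OLS."""

import numpy as np
import pytest

import habisuit as hs
from habisuit import (DegenerateInputError, GradeStats, ScenarioSpec,
                      ValidationError, average_over_gcms, pearson_corr,
                      project, threshold_regression)


def stats_with_high(high, total=100):
    rest = (100.0 - high) / 3.0
    props = {"unsuitable": rest, "marginal": rest, "moderate": rest,
             "high": high}
    counts = {g: int(round(total * p / 100)) for g, p in props.items()}
    counts["high"] += total - sum(counts.values())
    return GradeStats(counts=counts, proportions=props, total_valid=total)


class TestScenarioSpec:
    def test_valid_labels(self):
        spec = ScenarioSpec("A1B", "BC", "2050s")
        assert spec.label == "A1B-BC-2050s"

    @pytest.mark.parametrize("bad", [("A1C", "BC", "2050s"),
                                     ("A1B", "XX", "2050s"),
                                     ("A1B", "BC", "2030s")])
    def test_unknown_labels_rejected(self, bad):
        with pytest.raises(ValidationError):
            ScenarioSpec(*bad)


class TestProject:
    def test_identity_scenario_reproduces_present_bitwise(self, study_stack,
                                                          study_truth):
        present = hs.classify(hs.assess(study_stack, study_truth))
        result = project(study_truth, study_stack,
                         ScenarioSpec("B1", "CC", "2020s"))
        np.testing.assert_array_equal(result.grade_map.grades, present.grades)
        assert result.stats == hs.area_stats(present)

    def test_strong_warming_lowers_mean_suitability(self, study_stack,
                                                    study_truth):
        base = hs.assess(study_stack, study_truth)
        future = hs.uniform_warming(study_stack, 5.0)
        shifted = hs.assess(future, study_truth)
        valid = ~base.nodata_mask
        assert shifted.values[valid].mean() < base.values[valid].mean()

    def test_climate_summary_is_mean_over_valid_cells(self, study_stack,
                                                      study_truth):
        result = project(study_truth, study_stack,
                         ScenarioSpec("A2", "MI", "2080s"))
        valid = ~study_stack.nodata_mask
        assert result.bio1_mean == pytest.approx(
            study_stack.layer("Bio1")[valid].mean())
        assert result.bio12_mean == pytest.approx(
            study_stack.layer("Bio12")[valid].mean())


class TestAverageOverGcms:
    def _result(self, gcm, high):
        return hs.ScenarioResult(spec=ScenarioSpec("A1B", gcm, "2050s"),
                                 stats=stats_with_high(high),
                                 bio1_mean=12.0, bio12_mean=900.0)

    def test_identical_stats_unchanged(self):
        results = [self._result(g, 40.0) for g in ("BC", "CC", "MI")]
        avg = average_over_gcms(results)
        assert avg.proportions["high"] == pytest.approx(40.0)

    def test_arithmetic_mean_of_high_share(self):
        results = [self._result(g, h)
                   for g, h in zip(("BC", "CC", "MI"), (30.0, 40.0, 50.0))]
        avg = average_over_gcms(results)
        assert avg.proportions["high"] == pytest.approx(40.0)
        assert sum(avg.proportions.values()) == pytest.approx(100.0, abs=1e-6)

    def test_single_result_is_itself(self):
        avg = average_over_gcms([self._result("BC", 25.0)])
        assert avg.proportions["high"] == pytest.approx(25.0)

    def test_permutation_invariance(self):
        results = [self._result(g, h)
                   for g, h in zip(("BC", "CC", "MI"), (10.0, 60.0, 20.0))]
        a = average_over_gcms(results)
        b = average_over_gcms(results[::-1])
        assert a.proportions == b.proportions

    def test_mixed_specs_rejected(self):
        r1 = self._result("BC", 40.0)
        r2 = hs.ScenarioResult(spec=ScenarioSpec("A2", "CC", "2050s"),
                               stats=stats_with_high(40.0),
                               bio1_mean=12.0, bio12_mean=900.0)
        with pytest.raises(ValidationError):
            average_over_gcms([r1, r2])


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_corr(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_corr([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestThresholdRegression:
    def test_recovers_planted_intercept_exactly(self):
        bio1 = np.array([10.0, 12.0, 15.0, 18.0, 19.5])
        share = 100.0 - 5.0 * bio1
        fit = threshold_regression(bio1, share)
        assert fit.slope == pytest.approx(-5.0, abs=1e-9)
        assert fit.x_at_zero == pytest.approx(20.0, abs=1e-9)
        assert fit.threshold_valid
        assert fit.r == pytest.approx(-1.0, abs=1e-12)

    def test_noisy_monte_carlo_recovery(self):
        """Over 20 noise seeds the estimated extinction threshold must
        scatter tightly around the planted 20 degC."""
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bio1 = np.linspace(8, 19, 27)
            share = 100.0 - 5.0 * bio1 + rng.normal(0, 3.0, bio1.size)
            estimates.append(threshold_regression(bio1, share).x_at_zero)
        assert abs(np.mean(estimates) - 20.0) < 0.5
        assert np.std(estimates) < 1.0

    def test_zero_slope_flags_threshold_invalid(self):
        fit = threshold_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert not fit.threshold_valid
        assert np.isnan(fit.x_at_zero)

    def test_two_points_rejected(self):
        with pytest.raises(ValidationError):
            threshold_regression([1.0, 2.0], [3.0, 4.0])


class TestScenarioSuite:
    def test_warming_ladder_high_share_non_increasing(self, study_stack,
                                                      study_truth):
        shares = []
        for dt in range(7):
            future = hs.uniform_warming(study_stack, float(dt))
            result = project(study_truth, future,
                             ScenarioSpec("A1B", "BC", "2020s"))
            shares.append(result.stats.proportions["high"])
        assert all(a >= b - 1e-9 for a, b in zip(shares, shares[1:]))
        assert shares[-1] < shares[0]

    def test_warming_ladder_marginal_share_rises(self, study_stack,
                                                 study_truth):
        def marginal(dt):
            future = hs.uniform_warming(study_stack, dt)
            return project(study_truth, future,
                           ScenarioSpec("A1B", "BC", "2020s")
                           ).stats.proportions["marginal"]

        assert marginal(6.0) > marginal(0.0)

    def test_full_suite_correlations_are_negative_for_high(self, study_stack,
                                                           study_truth):
        results = hs.simulate_scenarios(study_truth, study_stack)
        assert len(results) == 27
        corr1 = hs.correlation_summary(results, "Bio1")
        corr12 = hs.correlation_summary(results, "Bio12")
        assert corr1["high"] < 0
        assert corr12["high"] < 0

    def test_results_table_is_tidy(self, study_stack, study_truth):
        results = hs.simulate_scenarios(
            study_truth, study_stack,
            [hs.ScenarioSpec("A1B", g, "2050s") for g in hs.GCMS])
        table = hs.scenarios.results_table(results)
        assert len(table) == 3 * 4
        assert set(table["grade"]) == set(hs.GRADE_LABELS)
        by_spec = table.groupby(["emission", "gcm", "period"])[
            "proportion_percent"].sum()
        assert np.allclose(by_spec, 100.0, atol=1e-6)
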