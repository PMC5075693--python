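"""Weighted aggregation, grade classification and area bookkeeping."""

import math

import numpy as np
import pytest

import habisuit as hs
from habisuit import (DegenerateInputError, GaussianMF, RampMF,
                      SuitabilityModel, SuitabilitySurface, ValidationError,
                      WeightVector, area_stats, assess, classify)


def make_model(weights, c_max=1.948):
    functions = {
        "Bio1": GaussianMF(a=10.3, sigma=3.5),
        "Bio12": GaussianMF(a=853.0, sigma=394.0),
    }
    return SuitabilityModel(functions=functions,
                            weights=WeightVector(weights), c_max=c_max)


class TestAssess:
    def test_all_optimal_cell_scores_one(self, tiny_stack):
        model = make_model({"Bio1": 0.4, "Bio12": 0.6})
        surface = assess(tiny_stack, model)
        # cell (0,0) holds both optima exactly
        assert surface.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_one_hot_weights_reproduce_single_layer(self, tiny_stack):
        model = make_model({"Bio1": 1.0, "Bio12": 0.0})
        surface = assess(tiny_stack, model)
        expected = model.functions["Bio1"](tiny_stack.layer("Bio1"))
        np.testing.assert_allclose(surface.values, expected, atol=1e-15)

    def test_equal_weights_average_two_degrees(self, tiny_transform):
        # layers engineered so memberships are exactly (0.2, 0.8)
        functions = {"Bio5": RampMF(zero_point=0.0, one_point=1.0),
                     "Bio6": RampMF(zero_point=0.0, one_point=1.0)}
        layers = {"Bio5": np.full((2, 2), 0.2), "Bio6": np.full((2, 2), 0.8)}
        stack = hs.BioclimStack(layers=layers, transform=tiny_transform,
                                nodata_mask=np.zeros((2, 2), bool))
        model = SuitabilityModel(
            functions=functions,
            weights=WeightVector({"Bio5": 0.5, "Bio6": 0.5}), c_max=1.0)
        surface = assess(stack, model)
        np.testing.assert_allclose(surface.values, 0.5, atol=1e-15)

    def test_missing_layer_rejected(self, tiny_stack):
        model = make_model({"Bio1": 0.5, "Bio12": 0.5})
        broken = hs.BioclimStack(layers={"Bio1": tiny_stack.layer("Bio1")},
                                 transform=tiny_stack.transform,
                                 nodata_mask=tiny_stack.nodata_mask)
        with pytest.raises(ValidationError):
            assess(broken, model)

    def test_nodata_propagates(self, tiny_transform):
        layers = {"Bio1": np.array([[10.3, 5.0], [0.0, 20.0]])}
        mask = np.array([[False, True], [False, False]])
        stack = hs.BioclimStack(layers=layers, transform=tiny_transform,
                                nodata_mask=mask)
        model = SuitabilityModel(functions={"Bio1": GaussianMF(10.3, 3.5)},
                                 weights=WeightVector({"Bio1": 1.0}),
                                 c_max=1.0)
        surface = assess(stack, model)
        assert np.isnan(surface.values[0, 1])
        assert surface.nodata_mask[0, 1]

    def test_brute_force_oracle_on_toy_stack(self, tiny_transform):
        """y_i must equal an independent cell-by-cell recomputation."""
        rng = np.random.default_rng(11)
        shape = (5, 5)
        layers = {"Bio1": rng.uniform(0, 20, shape),
                  "Bio12": rng.uniform(300, 1400, shape),
                  "Bio5": rng.uniform(20, 30, shape)}
        stack = hs.BioclimStack(layers=layers, transform=tiny_transform,
                                nodata_mask=np.zeros(shape, bool))
        model = SuitabilityModel(
            functions={"Bio1": GaussianMF(10.3, 3.5),
                       "Bio12": GaussianMF(853.0, 394.0),
                       "Bio5": RampMF(25.2, 26.7)},
            weights=WeightVector({"Bio1": 0.2, "Bio12": 0.5, "Bio5": 0.3}),
            c_max=1.948)
        surface = assess(stack, model)
        for r in range(shape[0]):
            for c in range(shape[1]):
                t1 = math.exp(-(((layers["Bio1"][r, c] - 10.3) / 3.5) ** 2))
                t2 = math.exp(-(((layers["Bio12"][r, c] - 853.0) / 394.0) ** 2))
                t5 = min(max((layers["Bio5"][r, c] - 25.2) / 1.5, 0.0), 1.0)
                y = 0.2 * t1 + 0.5 * t2 + 0.3 * t5
                assert surface.values[r, c] == pytest.approx(y, abs=1e-12)

    def test_monotone_in_any_single_membership(self, tiny_stack):
        model = make_model({"Bio1": 0.4, "Bio12": 0.6})
        surface = assess(tiny_stack, model)
        # moving Bio1 at cell (1,1) to its optimum cannot lower the index
        improved = {c: tiny_stack.layer(c).copy() for c in tiny_stack.codes}
        improved["Bio1"][1, 1] = 10.3
        stack2 = hs.BioclimStack(layers=improved,
                                 transform=tiny_stack.transform,
                                 nodata_mask=tiny_stack.nodata_mask)
        surface2 = assess(stack2, model)
        assert surface2.values[1, 1] >= surface.values[1, 1]

    def test_variable_order_invariance(self, tiny_stack):
        m1 = make_model({"Bio1": 0.4, "Bio12": 0.6})
        m2 = SuitabilityModel(
            functions={"Bio12": m1.functions["Bio12"],
                       "Bio1": m1.functions["Bio1"]},
            weights=WeightVector({"Bio12": 0.6, "Bio1": 0.4}), c_max=1.948)
        np.testing.assert_allclose(assess(tiny_stack, m1).values,
                                   assess(tiny_stack, m2).values, atol=1e-15)

    def test_mismatched_function_and_weight_codes_rejected(self):
        with pytest.raises(ValidationError):
            SuitabilityModel(functions={"Bio1": GaussianMF(10.3, 3.5)},
                             weights=WeightVector({"Bio2": 1.0}), c_max=1.0)


class TestClassify:
    @pytest.mark.parametrize("y, grade", [
        (0.0, 0), (0.29, 0), (0.30, 1), (0.49, 1),
        (0.50, 2), (0.69, 2), (0.70, 3), (1.0, 3),
    ])
    def test_half_open_binning_boundary_to_upper_grade(self, y, grade,
                                                       tiny_transform):
        surface = SuitabilitySurface(values=np.full((1, 1), y),
                                     transform=tiny_transform,
                                     nodata_mask=np.zeros((1, 1), bool))
        assert classify(surface).grades[0, 0] == grade

    @pytest.mark.parametrize("bad", [(0.5, 0.3, 0.7), (0.0, 0.5, 0.7),
                                     (0.3, 0.3, 0.7), (0.3, 0.5, 1.0)])
    def test_invalid_thresholds_rejected(self, bad, tiny_transform):
        surface = SuitabilitySurface(values=np.zeros((1, 1)),
                                     transform=tiny_transform,
                                     nodata_mask=np.zeros((1, 1), bool))
        with pytest.raises(ValidationError):
            classify(surface, bad)

    def test_custom_thresholds(self, tiny_transform):
        surface = SuitabilitySurface(values=np.array([[0.25]]),
                                     transform=tiny_transform,
                                     nodata_mask=np.zeros((1, 1), bool))
        assert classify(surface, (0.2, 0.4, 0.6)).grades[0, 0] == 1


class TestAreaStats:
    def _grade_map(self, grades, mask=None, transform=None):
        grades = np.asarray(grades)
        if mask is None:
            mask = np.zeros(grades.shape, bool)
        if transform is None:
            transform = hs.GeoTransform(0.0, 10.0, 0.1, 0.1)
        return hs.GradeMap(grades=grades, transform=transform,
                           nodata_mask=mask)

    def test_quartered_map(self):
        grades = np.repeat(np.arange(4), 25).reshape(10, 10)
        stats = area_stats(self._grade_map(grades))
        assert all(stats.proportions[g] == 25.0 for g in hs.GRADE_LABELS)
        assert stats.total_valid == 100

    def test_single_grade_map(self):
        stats = area_stats(self._grade_map(np.full((5, 5), 3)))
        assert stats.proportions == {"unsuitable": 0.0, "marginal": 0.0,
                                     "moderate": 0.0, "high": 100.0}

    def test_nodata_cells_excluded(self):
        grades = np.full((10, 10), 2)
        mask = np.ones((10, 10), bool)
        mask[0, :] = False  # 10 valid cells
        stats = area_stats(self._grade_map(grades, mask))
        assert stats.total_valid == 10
        assert stats.proportions["moderate"] == 100.0

    def test_counts_conserve_valid_cells(self, study_stack, study_truth):
        grade_map = classify(assess(study_stack, study_truth))
        stats = area_stats(grade_map)
        assert sum(stats.counts.values()) == study_stack.n_valid
        assert sum(stats.proportions.values()) == pytest.approx(100.0,
                                                                abs=1e-6)

    def test_no_valid_cells_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            area_stats(self._grade_map(np.zeros((3, 3), int),
                                       np.ones((3, 3), bool)))
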