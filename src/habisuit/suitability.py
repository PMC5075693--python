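"""Integrated ecological suitability: aggregation, grading, area statistics.

The fitted model combines one membership function per bioclimatic
variable with an entropy weight vector. At every grid cell *i* the
integrated ecological suitability index is the weighted average

    y_i = sum_j w_j * x_ij,

where ``x_ij`` is the membership degree of variable *j* at the cell.
Since memberships lie in [0, 1] and weights sum to 1, ``y_i`` lies in
[0, 1]: the closer to 1, the more the local climate favours both growth
and metabolite accumulation. The index is classified into four habitat
grades with half-open bins — unsuitable [0, 0.3), marginally suitable
[0.3, 0.5), moderately suitable [0.5, 0.7), highly suitable [0.7, 1] —
and grade areas are reported as percentages of valid (non-nodata) cells,
treating the ~1 km² cells as equal-area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .io import BioclimStack, GeoTransform, SampleSet
from .membership import (FitResult, MembershipFunction, fit_membership,
                         normalize_content, select_family)
from .weighting import WeightVector, entropy_weights

logger = logging.getLogger("habisuit")

#: grade codes and labels, in increasing suitability order
GRADE_LABELS: tuple[str, ...] = ("unsuitable", "marginal", "moderate", "high")
DEFAULT_THRESHOLDS: tuple[float, float, float] = (0.3, 0.5, 0.7)


@dataclass(frozen=True)
class SuitabilityModel:
    """Membership functions + weights + content normalization constant."""

    functions: Mapping[str, MembershipFunction]
    weights: WeightVector
    c_max: float

    def __post_init__(self):
        if set(self.functions) != set(self.weights.codes):
            raise ValidationError(
                "membership function codes and weight codes must be identical")
        if not np.isfinite(self.c_max) or self.c_max <= 0:
            raise ValidationError("c_max must be a positive finite percent")
        object.__setattr__(self, "functions", dict(self.functions))

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.functions)

    def memberships(self, values: np.ndarray,
                    codes: Sequence[str] | None = None) -> np.ndarray:
        """Evaluate per-variable memberships on an (n, n_codes) value array."""
        codes = self.codes if codes is None else tuple(codes)
        out = np.empty_like(np.asarray(values, dtype=float))
        for j, code in enumerate(codes):
            out[..., j] = self.functions[code](values[..., j])
        return out

    def index_of(self, values: np.ndarray,
                 codes: Sequence[str] | None = None) -> np.ndarray:
        """Weighted-average suitability index for rows of variable values."""
        codes = self.codes if codes is None else tuple(codes)
        x = self.memberships(np.asarray(values, dtype=float), codes)
        w = self.weights.as_array(codes)
        return x @ w


@dataclass
class SuitabilitySurface:
    """Per-cell suitability index in [0, 1] with shared georeferencing."""

    values: np.ndarray
    transform: GeoTransform
    nodata_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.nodata_mask.shape:
            raise ValidationError("surface and mask shapes differ")
        valid = self.values[~self.nodata_mask]
        if valid.size and (np.any(valid < -1e-12) or np.any(valid > 1 + 1e-12)):
            raise ValidationError("suitability index must lie in [0, 1]")


@dataclass
class GradeMap:
    """Four-grade classification of a suitability surface.

    ``grades`` holds codes 0..3 (unsuitable → high); nodata cells are
    flagged in ``nodata_mask`` and their code is meaningless.
    """

    grades: np.ndarray
    transform: GeoTransform
    nodata_mask: np.ndarray
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def __post_init__(self):
        self.grades = np.asarray(self.grades)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        _check_thresholds(self.thresholds)


@dataclass(frozen=True)
class GradeStats:
    """Cell counts and percentages per grade over valid cells."""

    counts: Mapping[str, int]
    proportions: Mapping[str, float]  # percent of valid cells
    total_valid: int

    def __post_init__(self):
        object.__setattr__(self, "counts", dict(self.counts))
        object.__setattr__(self, "proportions", dict(self.proportions))
        if sum(self.counts.values()) != self.total_valid:
            raise ValidationError("grade counts must sum to the valid-cell total")
        if abs(sum(self.proportions.values()) - 100.0) > 1e-6:
            raise ValidationError("grade proportions must sum to 100")

    def as_vector(self) -> np.ndarray:
        return np.array([self.proportions[g] for g in GRADE_LABELS])


def _check_thresholds(thresholds):
    t = tuple(float(v) for v in thresholds)
    if len(t) != 3 or not all(np.isfinite(t)):
        raise ValidationError("need three finite thresholds")
    if not (0.0 < t[0] < t[1] < t[2] < 1.0):
        raise ValidationError(
            f"thresholds must be strictly increasing within (0, 1): {t}")
    return t


def assess(stack: BioclimStack, model: SuitabilityModel) -> SuitabilitySurface:
    """Aggregate per-variable memberships into the suitability surface.

    Per valid cell: evaluate each variable's membership on its layer and
    take the weighted average. NaN in any layer marks the cell nodata in
    the output.
    """
    missing = [c for c in model.codes if c not in stack.layers]
    if missing:
        raise ValidationError(f"stack is missing model layer(s): {missing}")
    index = np.zeros(stack.shape, dtype=float)
    extra_nodata = np.zeros(stack.shape, dtype=bool)
    for code in model.codes:
        layer = stack.layer(code)
        bad = ~np.isfinite(layer)
        extra_nodata |= bad
        x = model.functions[code](np.where(bad, 0.0, layer))
        index += model.weights[code] * x
    mask = stack.nodata_mask | extra_nodata
    index[mask] = np.nan
    return SuitabilitySurface(values=index, transform=stack.transform,
                              nodata_mask=mask)


def classify(surface: SuitabilitySurface,
             thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> GradeMap:
    """Bin the index into four grades; boundary values go to the upper grade."""
    t1, t2, t3 = _check_thresholds(thresholds)
    vals = np.where(surface.nodata_mask, 0.0, surface.values)
    grades = np.digitize(vals, [t1, t2, t3], right=False).astype(np.uint8)
    return GradeMap(grades=grades, transform=surface.transform,
                    nodata_mask=surface.nodata_mask.copy(),
                    thresholds=(t1, t2, t3))


def area_stats(grade_map: GradeMap) -> GradeStats:
    """Per-grade cell counts and percentages of valid cells (equal-area)."""
    valid = ~grade_map.nodata_mask
    total = int(valid.sum())
    if total == 0:
        raise DegenerateInputError("grade map has no valid cells")
    g = grade_map.grades[valid]
    counts = {label: int((g == code).sum())
              for code, label in enumerate(GRADE_LABELS)}
    proportions = {label: 100.0 * counts[label] / total for label in GRADE_LABELS}
    return GradeStats(counts=counts, proportions=proportions, total_valid=total)


# ---------------------------------------------------------------------------
# model fitting pipeline
# ---------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    """Everything produced by :func:`fit_suitability_model`."""

    model: SuitabilityModel
    fit_results: dict[str, FitResult]
    train: SampleSet
    test: SampleSet
    split_seed: int


def fit_suitability_model(
    stack: BioclimStack,
    samples: SampleSet,
    families: Mapping[str, str] | None = None,
    train_frac: float = 0.75,
    seed: int = 0,
    codes: Sequence[str] | None = None,
) -> FittedPipeline:
    """Fit the full suitability model from a raster stack and sample table.

    Procedure: split the samples (75/25 by default, seeded), normalize
    contents to membership degrees by the maximum observed content,
    fit one membership curve per variable on the training split
    (family fixed per ``families`` or selected by best fitting degree),
    then derive entropy weights from the training membership matrix.

    Returns the fitted model together with per-variable fit diagnostics
    and the train/test split for downstream validation.
    """
    from .validation import split_samples  # local import to avoid a cycle

    codes = tuple(codes) if codes is not None else stack.codes
    train, test = split_samples(samples, train_frac=train_frac, seed=seed)

    values, inside = stack.values_at(train.lons, train.lats, codes)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("fit: %d training site(s) outside the stack extent "
                       "or on nodata cells were dropped", n_dropped)
    values = values[inside]
    if values.shape[0] < 4:
        raise ValidationError("fewer than 4 usable training sites")
    degrees, c_max = normalize_content(train.contents[inside])

    fit_results: dict[str, FitResult] = {}
    for j, code in enumerate(codes):
        xs = values[:, j]
        if families and code in families:
            fit_results[code] = fit_membership(xs, degrees, families[code])
        else:
            fit_results[code] = select_family(xs, degrees)

    membership_matrix = np.column_stack(
        [fit_results[c].function(values[:, j]) for j, c in enumerate(codes)]
    )
    weights = entropy_weights(membership_matrix, codes)
    model = SuitabilityModel(
        functions={c: fit_results[c].function for c in codes},
        weights=weights,
        c_max=c_max,
    )
    return FittedPipeline(model=model, fit_results=fit_results,
                          train=train, test=test, split_seed=seed)
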