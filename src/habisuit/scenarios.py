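"""Climate-scenario projection and climate–area relationships.

The fitted model is re-applied unchanged to future bioclimatic stacks
(one per emission scenario × general circulation model × period), the
grade areas are recomputed, and grade statistics are averaged across the
GCMs of each emission × period cell. Pooled across scenario runs, the
relationship between climate summaries (annual mean temperature Bio1,
annual precipitation Bio12, averaged over valid cells) and the
highly-suitable area share is quantified by Pearson correlation and by
ordinary least squares, whose x-intercept estimates the climate value at
which highly suitable habitat disappears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateInputError, ValidationError
from .io import BioclimStack
from .suitability import (DEFAULT_THRESHOLDS, GRADE_LABELS, GradeStats,
                          SuitabilityModel, area_stats, assess, classify)

logger = logging.getLogger("habisuit")

EMISSIONS: tuple[str, ...] = ("A1B", "A2", "B1")
GCMS: tuple[str, ...] = ("BC", "CC", "MI")
PERIODS: tuple[str, ...] = ("2020s", "2050s", "2080s")


@dataclass(frozen=True)
class ScenarioSpec:
    """A single (emission scenario, GCM, period) combination."""

    emission: str
    gcm: str
    period: str

    def __post_init__(self):
        if self.emission not in EMISSIONS:
            raise ValidationError(
                f"unknown emission scenario {self.emission!r}; expected {EMISSIONS}")
        if self.gcm not in GCMS:
            raise ValidationError(
                f"unknown GCM {self.gcm!r}; expected {GCMS}")
        if self.period not in PERIODS:
            raise ValidationError(
                f"unknown period {self.period!r}; expected {PERIODS}")

    @property
    def label(self) -> str:
        return f"{self.emission}-{self.gcm}-{self.period}"


@dataclass
class ScenarioResult:
    """Grade statistics and climate summary for one projected scenario."""

    spec: ScenarioSpec
    stats: GradeStats
    bio1_mean: float
    bio12_mean: float
    grade_map: object = None  # GradeMap, kept for identity checks / export


def project(model: SuitabilityModel, future: BioclimStack,
            spec: ScenarioSpec,
            thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> ScenarioResult:
    """Assess → classify → area statistics on a future stack.

    The climate summary is the mean of the Bio1 and Bio12 layers over the
    stack's valid cells (NaN if the layer is absent).
    """
    surface = assess(future, model)
    grade_map = classify(surface, thresholds)
    stats = area_stats(grade_map)
    valid = ~future.nodata_mask

    def layer_mean(code: str) -> float:
        if code not in future.layers:
            return float("nan")
        return float(future.layer(code)[valid].mean())

    return ScenarioResult(
        spec=spec,
        stats=stats,
        bio1_mean=layer_mean("Bio1"),
        bio12_mean=layer_mean("Bio12"),
        grade_map=grade_map,
    )


def average_over_gcms(results: Sequence[ScenarioResult]) -> GradeStats:
    """GCM-ensemble mean of grade proportions for one emission × period.

    The arithmetic mean of per-grade percentages is renormalized to sum
    exactly to 100 (guarding float drift); counts are reported as the
    rounded mean of member counts.
    """
    if not results:
        raise ValidationError("need at least one scenario result")
    keys = {(r.spec.emission, r.spec.period) for r in results}
    if len(keys) != 1:
        raise ValidationError(
            f"results mix emission/period combinations: {sorted(keys)}")
    props = np.mean([r.stats.as_vector() for r in results], axis=0)
    props = props * (100.0 / props.sum())
    mean_counts = np.mean(
        [[r.stats.counts[g] for g in GRADE_LABELS] for r in results], axis=0)
    counts = {g: int(round(c)) for g, c in zip(GRADE_LABELS, mean_counts)}
    total = sum(counts.values())
    # keep the count bookkeeping consistent after rounding
    counts[GRADE_LABELS[-1]] += int(np.mean([r.stats.total_valid
                                             for r in results]).round()) - total
    total = sum(counts.values())
    return GradeStats(
        counts=counts,
        proportions=dict(zip(GRADE_LABELS, props)),
        total_valid=total,
    )


def pearson_corr(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1 or xv.size < 3:
        raise ValidationError("need equal-length vectors with at least 3 points")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("constant input; correlation undefined")
    return float(sps.pearsonr(xv, yv).statistic)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of an area share on a climate summary.

    ``x_at_zero`` is the climate value where the fitted share reaches 0 —
    the estimated disappearance threshold — meaningful only when the
    slope is negative (``threshold_valid``).
    """

    slope: float
    intercept: float
    r: float
    p_value: float
    x_at_zero: float
    threshold_valid: bool


def threshold_regression(climate, proportions) -> RegressionResult:
    """Regress an area share (percent) on a climate summary by OLS."""
    xv = np.asarray(climate, dtype=float)
    yv = np.asarray(proportions, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1 or xv.size < 3:
        raise ValidationError("need equal-length vectors with at least 3 points")
    if np.ptp(xv) == 0:
        raise DegenerateInputError("constant climate summary; regression undefined")
    fit = sps.linregress(xv, yv)
    valid = fit.slope < 0
    x0 = -fit.intercept / fit.slope if fit.slope != 0 else float("nan")
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        x_at_zero=float(x0),
        threshold_valid=bool(valid),
    )


def results_table(results: Sequence[ScenarioResult]):
    """Tidy table of a scenario batch: one row per scenario × grade,
    with the climate summaries repeated per row (ready for CSV export)."""
    import pandas as pd

    rows = []
    for r in results:
        for grade in GRADE_LABELS:
            rows.append({
                "emission": r.spec.emission,
                "gcm": r.spec.gcm,
                "period": r.spec.period,
                "grade": grade,
                "proportion_percent": r.stats.proportions[grade],
                "cells": r.stats.counts[grade],
                "bio1_mean": r.bio1_mean,
                "bio12_mean": r.bio12_mean,
            })
    return pd.DataFrame(rows)


def correlation_summary(results: Sequence[ScenarioResult],
                        code: str = "Bio1") -> dict[str, float]:
    """Pearson correlation of one climate summary against each grade's
    share, pooled over all supplied scenario results."""
    attr = {"Bio1": "bio1_mean", "Bio12": "bio12_mean"}.get(code)
    if attr is None:
        raise ValidationError("correlation summary supports Bio1 and Bio12")
    x = [getattr(r, attr) for r in results]
    return {
        grade: pearson_corr(x, [r.stats.proportions[grade] for r in results])
        for grade in GRADE_LABELS
    }
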