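"""Entropy weighting of bioclimatic variables.

Weights are derived objectively from the dispersion of the
membership-standardized site × variable matrix, using Shannon entropy:
a variable whose standardized values vary strongly across sites carries
more discriminating information and receives a larger weight, while a
near-constant variable contributes almost nothing. For m sites:

    p_ij = x_ij / sum_i x_ij
    e_j  = -(1 / ln m) * sum_i p_ij ln p_ij      (0 * ln 0 := 0)
    d_j  = 1 - e_j
    w_j  = d_j / sum_j d_j

An all-zero column is degenerate (p undefined); it is assigned weight 0
with a warning, since an everywhere-unsuitable variable carries no
discriminating information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DegenerateInputError, ValidationError

logger = logging.getLogger("habisuit")

_WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative per-variable weights summing to 1."""

    weights: Mapping[str, float]

    def __post_init__(self):
        w = np.array(list(self.weights.values()), dtype=float)
        if w.size == 0:
            raise ValidationError("weight vector is empty")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValidationError("weights must be finite and nonnegative")
        if abs(w.sum() - 1.0) > _WEIGHT_SUM_TOL:
            raise ValidationError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "weights", dict(self.weights))

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def __getitem__(self, code: str) -> float:
        return self.weights[code]

    def as_array(self, codes: Sequence[str] | None = None) -> np.ndarray:
        codes = self.codes if codes is None else tuple(codes)
        return np.array([self.weights[c] for c in codes], dtype=float)

    def as_percent(self) -> dict[str, float]:
        return {c: 100.0 * w for c, w in self.weights.items()}


def entropy_weights(matrix, codes: Sequence[str] | None = None) -> WeightVector:
    """Entropy weights of a sites × variables membership matrix.

    Parameters
    ----------
    matrix : (m, n) array-like with entries in [0, 1], m >= 2 sites
    codes : variable names for the n columns; defaults to ``var1..varn``

    Returns
    -------
    WeightVector mapping each code to its weight (fractions summing to 1).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("matrix must be 2-D (sites x variables)")
    m, n = x.shape
    if m < 2:
        raise ValidationError(f"need at least 2 sites, got {m}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("matrix entries must be finite")
    if np.any(x < 0):
        raise ValidationError("matrix entries must be nonnegative")
    if np.any(x > 1):
        raise ValidationError("matrix entries must lie in [0, 1]")
    if codes is None:
        codes = tuple(f"var{j + 1}" for j in range(n))
    else:
        codes = tuple(codes)
        if len(codes) != n:
            raise ValidationError("codes length must match the number of columns")

    col_sums = x.sum(axis=0)
    zero_cols = col_sums == 0
    if np.any(zero_cols):
        logger.warning(
            "entropy_weights: %d all-zero column(s) assigned weight 0: %s",
            int(zero_cols.sum()),
            [codes[j] for j in np.flatnonzero(zero_cols)],
        )

    d = np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(n):
            if zero_cols[j]:
                continue
            p = x[:, j] / col_sums[j]
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
            e_j = -plogp.sum() / np.log(m)
            d[j] = max(1.0 - e_j, 0.0)

    # a constant column has d_j = 0 exactly in the mathematics; snap the
    # float-roundoff residue (~1e-16) so it cannot masquerade as signal
    d[d <= 1e-12] = 0.0
    total = d.sum()
    if total == 0:
        raise DegenerateInputError(
            "every column is constant; entropy weights are undefined"
        )
    w = d / total
    return WeightVector(dict(zip(codes, w)))


def column_summary(values: Sequence[float]) -> tuple[float, float, float]:
    """(min, max, mean-rounded-to-2-decimals) of a printed column of values.

    Used to summarize per-variable statistics such as the 19 fitting
    degrees of the reference fit.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValidationError("empty column")
    if not np.all(np.isfinite(v)):
        raise ValidationError("column values must be finite")
    return float(v.min()), float(v.max()), round(float(v.mean()), 2)
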