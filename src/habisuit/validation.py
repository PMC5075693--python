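"""Hold-out validation of the suitability model.

Samples are partitioned once into a training and a test split (75/25 by
default, seeded). Model skill is scored on the membership scale by
comparing the predicted suitability index at each test site's grid cell
(P) against the site's normalized content (Q):

    RMSE = sqrt( (1/N) * sum (P_i - Q_i)^2 )
    R^2  = 1 - sum (Q_i - P_i)^2 / sum (Q_i - Qbar)^2

R² is reported as computed — it can go negative out of sample for a
predictor worse than the observed mean; no clamping is applied. The
same routine runs unchanged on external sites outside the training
region, which is how model transferability is checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .io import BioclimStack, SampleSet
from .suitability import SuitabilityModel

logger = logging.getLogger("habisuit")


def split_samples(samples: SampleSet, train_frac: float = 0.75,
                  seed: int = 0) -> tuple[SampleSet, SampleSet]:
    """Disjoint, exhaustive, seeded random partition of a sample set.

    ``|train| = round(train_frac * n)`` (banker's rounding), nudged by one
    if either side would be empty. The same seed always yields the same
    partition.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValidationError("train_frac must lie strictly between 0 and 1")
    n = len(samples)
    if n < 4:
        raise ValidationError(f"need at least 4 samples to split, got {n}")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return samples.subset(train_idx), samples.subset(test_idx)


def rmse(pred, obs) -> float:
    """Root mean square error between predictions and observations."""
    p = np.asarray(pred, dtype=float)
    q = np.asarray(obs, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or p.size == 0:
        raise ValidationError("pred and obs must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((p - q) ** 2)))


def r_squared(pred, obs) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (not clamped)."""
    p = np.asarray(pred, dtype=float)
    q = np.asarray(obs, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or p.size < 2:
        raise ValidationError("pred and obs must be equal-length vectors (n >= 2)")
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("observations are constant; R^2 undefined")
    return 1.0 - float(np.sum((q - p) ** 2)) / ss_tot


@dataclass(frozen=True)
class ValidationReport:
    """RMSE / R² on a hold-out split, with bookkeeping."""

    rmse: float
    r_squared: float
    n_train: int
    n_test: int
    n_excluded: int
    split_seed: int | None

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_excluded": self.n_excluded,
            "split_seed": self.split_seed,
        }


def validate_model(model: SuitabilityModel, stack: BioclimStack,
                   test: SampleSet, n_train: int = 0,
                   split_seed: int | None = None,
                   c_max: float | None = None) -> ValidationReport:
    """Score the model on held-out sites.

    P_i is the suitability index computed from the stack values at each
    test site's cell; Q_i is the site's content normalized by ``c_max``
    (the model's constant by default, so train and test share the same
    membership scale). Sites outside the extent or on nodata cells are
    excluded with a warning.
    """
    values, inside = stack.values_at(test.lons, test.lats, model.codes)
    n_excluded = int((~inside).sum())
    if n_excluded:
        logger.warning("validate: excluding %d site(s) outside the stack "
                       "extent or on nodata cells", n_excluded)
    if not inside.any():
        raise ValidationError("no test site falls on a valid cell")
    pred = model.index_of(values[inside])
    scale = model.c_max if c_max is None else c_max
    obs = np.clip(test.contents[inside] / scale, 0.0, 1.0)
    return ValidationReport(
        rmse=rmse(pred, obs),
        r_squared=r_squared(pred, obs),
        n_train=int(n_train),
        n_test=int(inside.sum()),
        n_excluded=n_excluded,
        split_seed=split_seed,
    )
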