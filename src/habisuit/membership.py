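"""Fuzzy membership functions linking bioclimatic variables to suitability.

A membership function maps an environmental variable to a suitability
degree in [0, 1]: 1 means the variable sits at its optimum for synthesis
and accumulation of the marker metabolite, 0 means complete
non-membership (the plant cannot grow, or cannot accumulate the
metabolite, under that value). Three families are supported:

``gaussian``
    ``A(x) = exp(-((x - a) / sigma)**2)`` — unimodal, symmetric about the
    optimum ``a``; used for variables with both lower and upper limiting
    boundaries.
``two_sided_gaussian``
    A piecewise Gaussian with independent left/right widths about a shared
    optimum; used where tolerance is asymmetric around the optimum.
``ramp``
    The trapezoidal shoulder ``clip((x - z) / (o - z), 0, 1)`` between a
    zero-point ``z`` and a one-point ``o``; ascending when ``o > z``
    (variables with only a lower limiting boundary) and descending when
    ``o < z`` (only an upper boundary).

Observed metabolite contents are standardized to degrees by dividing by
the maximum observed content (``c_max``), so the best observed sample
defines complete membership. Curves are fitted to (variable value,
degree) pairs by bounded nonlinear least squares; goodness of fit is
reported as a *fitting degree*, ``100 * (1 - RMSE)`` on the membership
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Union

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateInputError, DomainError, FitError, ValidationError

logger = logging.getLogger("habisuit")

Family = Literal["gaussian", "two_sided_gaussian", "ramp"]
FAMILIES: tuple[Family, ...] = ("gaussian", "two_sided_gaussian", "ramp")

#: optimizer settings for curve fitting (relative tolerance, evaluation cap)
FIT_XTOL = 1e-8
FIT_MAX_NFEV = 10_000

_SIGMA_FLOOR = 1e-12


@dataclass(frozen=True)
class GaussianMF:
    """``A(x) = exp(-((x - a) / sigma)**2)``; attains exactly 1 at x = a."""

    a: float
    sigma: float

    family: str = "gaussian"

    def __post_init__(self):
        if not np.isfinite(self.a) or not np.isfinite(self.sigma):
            raise ValidationError("gaussian parameters must be finite")
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return np.exp(-(((x - self.a) / self.sigma) ** 2))

    def params(self) -> dict:
        return {"a": self.a, "sigma": self.sigma}


@dataclass(frozen=True)
class TwoSidedGaussianMF:
    """Piecewise Gaussian: width ``sigma_left`` below the optimum ``a`` and
    ``sigma_right`` at or above it. Continuous at x = a with value 1."""

    a: float
    sigma_left: float
    sigma_right: float

    family: str = "two_sided_gaussian"

    def __post_init__(self):
        for name in ("a", "sigma_left", "sigma_right"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.sigma_left <= 0 or self.sigma_right <= 0:
            raise ValidationError("two-sided gaussian widths must be > 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        sigma = np.where(x < self.a, self.sigma_left, self.sigma_right)
        return np.exp(-(((x - self.a) / sigma) ** 2))

    def params(self) -> dict:
        return {
            "a": self.a,
            "sigma_left": self.sigma_left,
            "sigma_right": self.sigma_right,
        }


@dataclass(frozen=True)
class RampMF:
    """Trapezoidal shoulder between ``zero_point`` (membership 0) and
    ``one_point`` (membership 1), affine in between; orientation follows the
    order of the two points, so ``one_point < zero_point`` yields the
    descending variant."""

    zero_point: float
    one_point: float

    family: str = "ramp"

    def __post_init__(self):
        if not np.isfinite(self.zero_point) or not np.isfinite(self.one_point):
            raise ValidationError("ramp endpoints must be finite")
        if self.zero_point == self.one_point:
            raise ValidationError("ramp endpoints must differ")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(over="ignore"):  # clip absorbs any overflow to +/-inf
            t = (x - self.zero_point) / (self.one_point - self.zero_point)
        return np.clip(t, 0.0, 1.0)

    def params(self) -> dict:
        return {"zero_point": self.zero_point, "one_point": self.one_point}


MembershipFunction = Union[GaussianMF, TwoSidedGaussianMF, RampMF]

_FAMILY_CLASSES = {
    "gaussian": GaussianMF,
    "two_sided_gaussian": TwoSidedGaussianMF,
    "ramp": RampMF,
}


def membership_from_dict(d: dict) -> MembershipFunction:
    """Rebuild a membership function from its serialized form
    ``{"family": ..., "params": {...}}``."""
    try:
        cls = _FAMILY_CLASSES[d["family"]]
    except KeyError as exc:
        raise ValidationError(f"unknown membership family: {d.get('family')!r}") from exc
    return cls(**d["params"])


def membership_to_dict(f: MembershipFunction) -> dict:
    return {"family": f.family, "params": f.params()}


def eval_membership(f: MembershipFunction, x) -> np.ndarray | float:
    """Evaluate a membership function, guarding the domain.

    Parameters
    ----------
    f : membership function
    x : scalar or array of finite variable values

    Returns
    -------
    degree(s) in [0, 1], scalar if ``x`` is scalar.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("membership argument must be finite")
    out = f(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def normalize_content(contents: Iterable[float]) -> tuple[np.ndarray, float]:
    """Standardize metabolite contents (percent) to membership degrees.

    The degree of sample *i* is ``content_i / max(contents)``: the best
    observed sample defines complete membership (degree 1), and
    low-but-nonzero contents map to partial membership rather than zero.

    Returns
    -------
    (degrees, c_max)
        degrees in [0, 1] and the normalization constant ``c_max`` (the
        maximum observed content, in percent) to be stored with the model.
    """
    c = np.asarray(list(contents) if not isinstance(contents, np.ndarray) else contents,
                   dtype=float)
    if c.size == 0:
        raise ValidationError("contents is empty")
    if not np.all(np.isfinite(c)):
        raise ValidationError("contents must be finite")
    if np.any(c < 0):
        raise ValidationError("contents must be nonnegative")
    c_max = float(c.max())
    if c_max == 0.0:
        raise DegenerateInputError("all contents are zero; degrees undefined")
    return c / c_max, c_max


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one membership curve.

    ``fitting_degree`` is ``100 * (1 - residual_rmse)`` clipped to
    [0, 100] — a 0–100 goodness-of-fit scale natural for residuals on the
    bounded membership scale. ``r_squared`` is logged alongside for
    transparency.
    """

    function: MembershipFunction
    fitting_degree: float
    n_points: int
    residual_rmse: float
    r_squared: float

    def to_dict(self) -> dict:
        d = membership_to_dict(self.function)
        d.update(
            fitting_degree=self.fitting_degree,
            n_points=self.n_points,
            residual_rmse=self.residual_rmse,
            r_squared=self.r_squared,
        )
        return d


def _fitting_degree(rmse: float) -> float:
    return float(np.clip(100.0 * (1.0 - rmse), 0.0, 100.0))


def _initial_guess(family: Family, xs: np.ndarray, ys: np.ndarray):
    """Data-driven starting point and bounds for the optimizer."""
    lo, hi = float(xs.min()), float(xs.max())
    span = hi - lo
    if family == "gaussian":
        a0 = float(xs[np.argmax(ys)])
        s0 = span / 2.0
        return [a0, s0], ([-np.inf, _SIGMA_FLOOR], [np.inf, np.inf])
    if family == "two_sided_gaussian":
        a0 = float(xs[np.argmax(ys)])
        s0 = span / 2.0
        return [a0, s0, s0], ([-np.inf, _SIGMA_FLOOR, _SIGMA_FLOOR],
                              [np.inf, np.inf, np.inf])
    # ramp: endpoint order follows the sign of the degree-value correlation
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(xs, ys)[0, 1]
    if np.isnan(corr) or corr >= 0:
        z0, o0 = lo, hi
    else:
        z0, o0 = hi, lo
    return [z0, o0], ([-np.inf, -np.inf], [np.inf, np.inf])


def _build(family: Family, params: np.ndarray) -> MembershipFunction:
    if family == "gaussian":
        return GaussianMF(float(params[0]), float(max(params[1], _SIGMA_FLOOR)))
    if family == "two_sided_gaussian":
        return TwoSidedGaussianMF(
            float(params[0]),
            float(max(params[1], _SIGMA_FLOOR)),
            float(max(params[2], _SIGMA_FLOOR)),
        )
    return RampMF(float(params[0]), float(params[1]))


def fit_membership(xs, degrees, family: Family) -> FitResult:
    """Fit one membership family to observed (variable, degree) pairs.

    Parameters
    ----------
    xs : array of variable values at the sample sites
    degrees : array of normalized contents in [0, 1], same length
    family : one of ``gaussian``, ``two_sided_gaussian``, ``ramp``

    Returns
    -------
    FitResult with the least-squares estimate and its fitting degree.
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown family: {family!r}")
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(degrees, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValidationError("xs and degrees must be 1-D arrays of equal length")
    if xs.size < 4:
        raise ValidationError(f"need at least 4 points to fit, got {xs.size}")
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
        raise ValidationError("xs and degrees must be finite")
    if np.all(xs == xs[0]):
        raise DegenerateInputError("variable values are constant; curve undefined")
    if np.any((ys < 0) | (ys > 1)):
        raise ValidationError("degrees must lie in [0, 1]")

    x0, bounds = _initial_guess(family, xs, ys)

    def residuals(p):
        try:
            f = _build(family, p)
        except ValidationError:
            return np.full(xs.size, 1e3)
        return f(xs) - ys

    try:
        sol = least_squares(
            residuals, x0, bounds=bounds, xtol=FIT_XTOL, max_nfev=FIT_MAX_NFEV
        )
    except Exception as exc:  # pragma: no cover - optimizer internal failure
        raise FitError(f"membership fit failed for family {family}",
                       {"family": family, "exception": repr(exc)}) from exc
    if not sol.success:
        raise FitError(
            f"membership fit did not converge for family {family}",
            {"family": family, "status": sol.status, "message": sol.message},
        )

    f = _build(family, sol.x)
    resid = f(xs) - ys
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return FitResult(
        function=f,
        fitting_degree=_fitting_degree(rmse),
        n_points=int(xs.size),
        residual_rmse=rmse,
        r_squared=r2,
    )


#: preference order when fitting degrees tie: fewest assumptions first
_FAMILY_PREFERENCE: tuple[Family, ...] = ("gaussian", "two_sided_gaussian", "ramp")


def select_family(xs, degrees) -> FitResult:
    """Fit all three families and return the best by fitting degree.

    Exact ties are broken by the preference order
    gaussian > two_sided_gaussian > ramp. Families whose fit fails to
    converge are skipped (with a log record); if none converge the last
    failure is raised.
    """
    best: FitResult | None = None
    last_err: FitError | None = None
    for family in _FAMILY_PREFERENCE:
        try:
            result = fit_membership(xs, degrees, family)
        except FitError as exc:
            logger.warning("family %s failed to converge: %s", family, exc)
            last_err = exc
            continue
        if best is None or result.fitting_degree > best.fitting_degree:
            best = result
    if best is None:
        assert last_err is not None
        raise last_err
    return best
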