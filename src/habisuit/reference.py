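"""Published reference fit for schisantherin-A habitat suitability.

This module bundles, as plain constants, the published membership-model
summary for *Schisandra sphenanthera* in the Qinling Mountains: for each
of the 19 bioclimatic variables (Bio1–Bio19) the fitted membership family,
its optimum, the printed threshold pair, the fitting degree (percent) and
the entropy weight (percent). The constants serve two purposes:

* fixtures for evaluation tests and summary statistics of the reference
  fit (fitting degrees range 76.20–96.93 %, mean 84.09 %; weights sum to
  100.00 %);
* the default *planted truth* of the synthetic-data generator, so that
  simulated landscapes carry realistic optima (e.g. annual mean
  temperature 10.3 °C, annual precipitation 853 mm).

Planted widths are chosen so that membership equals 0.5 at the printed
threshold pair (``sigma = halfwidth / sqrt(ln 2)``); default variable
ranges anchor each curve's membership-1 point at a common relative
position so that the generator's co-varying layers align their optima
on a shared latent gradient (see :mod:`habisuit.synthetic`).

Notes on individual rows (documented quirks of the printed table):

* Bio4's threshold pair is internally inconsistent (4.03 below the
  optimum 83.10); the symmetric completion of the 72.16 side is used.
* Bio19 prints a single threshold; a symmetric width is used.
* Bio9 and Bio11 print extremely wide thresholds (±25 °C, near-flat
  curves); their default range widths are capped at a realistic 30 °C
  and the planted widths scaled down with the cap, so the synthetic
  curves stay identifiable.
* Bio7 is generated as Bio5 − Bio6, so its planted optimum is the value
  implied by the Bio5/Bio6 range midpoints (29.4 °C) rather than the
  printed 33.0 °C, which is incompatible with that identity under the
  centred default ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .membership import GaussianMF, MembershipFunction, RampMF, TwoSidedGaussianMF

#: Bio-variable codes in canonical order.
BIOCLIM_CODES: tuple[str, ...] = tuple(f"Bio{i}" for i in range(1, 20))

#: Human-readable descriptions of the 19 bioclimatic variables.
BIOCLIM_DESCRIPTIONS: dict[str, str] = {
    "Bio1": "Annual mean temperature (degC)",
    "Bio2": "Mean diurnal temperature range (degC)",
    "Bio3": "Isothermality (Bio2/Bio7)",
    "Bio4": "Temperature seasonality (std dev x100)",
    "Bio5": "Max temperature of warmest month (degC)",
    "Bio6": "Min temperature of coldest month (degC)",
    "Bio7": "Temperature annual range (Bio5-Bio6) (degC)",
    "Bio8": "Mean temperature of wettest quarter (degC)",
    "Bio9": "Mean temperature of driest quarter (degC)",
    "Bio10": "Mean temperature of warmest quarter (degC)",
    "Bio11": "Mean temperature of coldest quarter (degC)",
    "Bio12": "Annual precipitation (mm)",
    "Bio13": "Precipitation of wettest month (mm)",
    "Bio14": "Precipitation of driest month (mm)",
    "Bio15": "Precipitation seasonality (CV)",
    "Bio16": "Precipitation of wettest quarter (mm)",
    "Bio17": "Precipitation of driest quarter (mm)",
    "Bio18": "Precipitation of warmest quarter (mm)",
    "Bio19": "Precipitation of coldest quarter (mm)",
}

#: Absolute-temperature layers (shift additively under uniform warming).
TEMPERATURE_CODES: frozenset[str] = frozenset(
    {"Bio1", "Bio5", "Bio6", "Bio8", "Bio9", "Bio10", "Bio11"}
)
#: Precipitation-amount layers (scale multiplicatively in delta scenarios).
PRECIPITATION_CODES: frozenset[str] = frozenset(
    {"Bio12", "Bio13", "Bio14", "Bio16", "Bio17", "Bio18", "Bio19"}
)


@dataclass(frozen=True)
class ReferenceRow:
    """One row of the published reference fit."""

    code: str
    family: str  # printed label: gaussian / two_sided_gaussian / ramp_up / ramp_down
    optimum: float
    thresholds: tuple[float, ...]
    fitting_degree: float
    weight_percent: float


#: The published per-variable summary (families, optima, printed threshold
#: values, fitting degrees in percent, entropy weights in percent).
REFERENCE_TABLE: tuple[ReferenceRow, ...] = (
    ReferenceRow("Bio1", "gaussian", 10.3, (7.3, 13.2), 85.44, 6.37),
    ReferenceRow("Bio2", "two_sided_gaussian", 88.4, (70.0, 135.0), 85.70, 5.48),
    ReferenceRow("Bio3", "gaussian", 0.26, (0.22, 0.31), 80.52, 3.74),
    ReferenceRow("Bio4", "gaussian", 83.10, (72.16, 4.03), 80.36, 4.13),
    ReferenceRow("Bio5", "ramp_up", 26.70, (25.20,), 89.02, 3.33),
    ReferenceRow("Bio6", "ramp_up", -2.70, (-8.60,), 83.50, 3.74),
    ReferenceRow("Bio7", "gaussian", 33.00, (30.10, 35.80), 80.81, 7.10),
    ReferenceRow("Bio8", "ramp_down", 18.10, (23.00,), 93.40, 5.21),
    ReferenceRow("Bio9", "gaussian", 5.60, (-20.00, 32.00), 79.54, 1.34),
    ReferenceRow("Bio10", "ramp_down", 19.20, (23.80,), 96.93, 5.36),
    ReferenceRow("Bio11", "gaussian", 4.04, (-21.0, 29.0), 76.63, 5.31),
    ReferenceRow("Bio12", "gaussian", 853.00, (525.00, 1181.00), 77.34, 6.51),
    ReferenceRow("Bio13", "gaussian", 144.00, (96.00, 192.00), 86.52, 5.92),
    ReferenceRow("Bio14", "gaussian", 10.14, (0.94, 19.00), 81.27, 5.49),
    ReferenceRow("Bio15", "gaussian", 0.70, (0.56, 0.82), 84.27, 5.82),
    ReferenceRow("Bio16", "gaussian", 415.20, (294.00, 536.00), 84.97, 6.79),
    ReferenceRow("Bio17", "gaussian", 36.11, (7.17, 65.04), 78.75, 5.76),
    ReferenceRow("Bio18", "gaussian", 367.20, (251.00, 483.00), 76.20, 6.66),
    ReferenceRow("Bio19", "two_sided_gaussian", 27.77, (5.36,), 96.60, 5.94),
)

REFERENCE_FITTING_DEGREES: dict[str, float] = {
    r.code: r.fitting_degree for r in REFERENCE_TABLE
}
REFERENCE_WEIGHTS_PERCENT: dict[str, float] = {
    r.code: r.weight_percent for r in REFERENCE_TABLE
}

# membership = 0.5 at the printed threshold: sigma = halfwidth / sqrt(ln 2)
_HALF_CUT = math.sqrt(math.log(2.0))

# Planted gaussian half-widths (variable units) derived from the printed
# threshold pairs, with the documented completions for Bio4 and Bio19.
_PLANTED_HALFWIDTH: dict[str, float] = {
    "Bio1": 2.95,
    "Bio3": 0.045,
    "Bio4": 83.10 - 72.16,        # symmetric completion of the valid side
    "Bio7": 2.85,
    "Bio9": 26.0,
    "Bio11": 25.0,
    "Bio12": 328.0,
    "Bio13": 48.0,
    "Bio14": 9.06,                # mean of (10.14-0.94, 19.00-10.14)
    "Bio15": 0.13,
    "Bio16": 121.0,
    "Bio17": 28.935,
    "Bio18": 116.1,
}
# two-sided: (left halfwidth, right halfwidth)
_PLANTED_TWO_SIDED: dict[str, tuple[float, float]] = {
    "Bio2": (88.4 - 70.0, 135.0 - 88.4),
    "Bio19": (27.77 - 5.36, 27.77 - 5.36),  # single printed threshold
}
# ramps: (zero_point, one_point)
_PLANTED_RAMP: dict[str, tuple[float, float]] = {
    "Bio5": (25.20, 26.70),
    "Bio6": (-8.60, -2.70),
    "Bio8": (23.00, 18.10),
    "Bio10": (23.80, 19.20),
}

#: Cap on range width for the widest-threshold temperature curves (degC).
_TEMP_WIDTH_CAP = 30.0
#: Planted Bio7 optimum implied by the Bio5/Bio6 range anchors.
BIO7_DERIVED_OPTIMUM = 26.70 - (-2.70)
#: Default relative position of each membership-1 point within its range.
DEFAULT_OPTIMUM_QUANTILE = 0.4


def planted_defaults(optimum_quantile: float = DEFAULT_OPTIMUM_QUANTILE
                     ) -> tuple[dict[str, MembershipFunction],
                                dict[str, tuple[float, float]]]:
    """Default planted truth and generator value ranges, built together.

    Every variable's membership-1 point (Gaussian optimum, ramp
    one-point) sits at the same relative position ``optimum_quantile``
    within its range, so optima align on the generator's shared latent
    gradient. The default 0.4 places the optimum in the cooler, drier
    part of the landscape: most cells are warmer and wetter than
    optimal, the regime in which further warming erodes highly suitable
    habitat (only the minority of cells below the optimum gain).

    Range widths are 6 planted halfwidths for Gaussian rows (both tails
    of the curve reach ≈ 0 inside the range, keeping the fitted location
    unbiased), 3 × (left + right halfwidth) for two-sided rows and
    3 × shoulder length for ramps; temperature widths are capped at
    30 °C and precipitation ranges clamped to nonnegative values.
    Planted curve widths scale with any clamping (``sigma = width / 5``,
    which reduces to the printed-threshold sigma whenever the range is
    unclamped), so every curve keeps the same shape relative to its
    landscape span. Bio7 has no configured range — it is derived as
    Bio5 − Bio6.
    """
    q = optimum_quantile
    if not 1.0 / 3.0 <= q <= 0.5:
        raise ValueError("optimum_quantile must lie in [1/3, 1/2]")
    functions: dict[str, MembershipFunction] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for row in REFERENCE_TABLE:
        code = row.code
        if code in _PLANTED_RAMP:
            z, o = _PLANTED_RAMP[code]
            # ramp widths never hit the caps (all well under 30 degC)
            functions[code] = RampMF(zero_point=z, one_point=o)
            width = 3.0 * abs(o - z)
            ranges[code] = (o - q * width, o + (1.0 - q) * width)
            continue
        if code in _PLANTED_TWO_SIDED:
            hl, hr = _PLANTED_TWO_SIDED[code]
            anchor = row.optimum
            width0 = 3.0 * (hl + hr)
        else:
            anchor = BIO7_DERIVED_OPTIMUM if code == "Bio7" else row.optimum
            hl = hr = _PLANTED_HALFWIDTH[code]
            width0 = 6.0 * hl
        width = width0
        if code in TEMPERATURE_CODES:
            width = min(width, _TEMP_WIDTH_CAP)
        if code in PRECIPITATION_CODES:
            width = min(width, anchor / q)  # nonnegative precipitation
        scale = width / width0
        if code in _PLANTED_TWO_SIDED:
            functions[code] = TwoSidedGaussianMF(
                a=anchor,
                sigma_left=scale * hl / _HALF_CUT,
                sigma_right=scale * hr / _HALF_CUT,
            )
        else:
            functions[code] = GaussianMF(a=anchor, sigma=scale * hl / _HALF_CUT)
        if code != "Bio7":
            ranges[code] = (anchor - q * width, anchor + (1.0 - q) * width)
    return functions, ranges


def planted_membership_functions(
        optimum_quantile: float = DEFAULT_OPTIMUM_QUANTILE
) -> dict[str, MembershipFunction]:
    """The default planted truth: one membership function per variable."""
    return planted_defaults(optimum_quantile)[0]


def default_variable_ranges(
        optimum_quantile: float = DEFAULT_OPTIMUM_QUANTILE
) -> dict[str, tuple[float, float]]:
    """Default generator value ranges (see :func:`planted_defaults`)."""
    return planted_defaults(optimum_quantile)[1]
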