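"""Synthetic landscapes, samples and scenarios for end-to-end testing.

Real inputs to the pipeline — 30-arc-second bioclim rasters and field
samples of fruit metabolite content — are large downloads and private
field campaigns. This module generates structurally faithful stand-ins:

* **Stacks** of 19 co-registered layers built from a shared latent
  gradient (an affine spatial trend plus moving-average-smoothed noise)
  mixed with per-variable smoothed noise and rescaled into realistic
  per-variable ranges. The shared gradient makes the layers strongly
  co-vary, as real bioclimatic variables do along elevation gradients;
  the mixing coefficient ``cross_corr`` controls how strongly. The
  derived identity Bio7 = Bio5 − Bio6 is honoured by construction.
* **Planted truth**: the default membership functions come from the
  published reference fit (module :mod:`habisuit.reference`); the planted
  weight vector defaults to uniform. Uniform is the fixed point of the
  fit→weight loop under co-varying layers: every fitted membership
  column approximates the same aggregate signal, so the entropy method
  returns near-uniform weights whatever vector generated the data —
  weights are only weakly identifiable from aggregate content, and only
  a near-uniform planting makes full-loop recovery well-posed.
* **Samples** at random valid cells with content
  ``clip(y_true + eps, 0, 1) * c_max``, ``eps ~ N(0, noise_sd)`` on the
  membership scale; a redraw guard keeps at least one content within 1 %
  of ``c_max`` so content normalization is anchored.
* **Future stacks** by the delta method: additive shifts on absolute
  temperature layers, multiplicative factors on precipitation amounts,
  with mask and georeferencing unchanged.

Because every variable's membership-1 point sits at the same relative
position of its configured range (default: quantile 0.35, a landscape
mostly warmer and wetter than optimal), the optima align on the latent
gradient: the aggregate index peaks where every variable is optimal,
and each variable's marginal relation to observed degrees traces its
own planted curve. All randomness flows through a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.ndimage import uniform_filter

from .exceptions import ValidationError
from .io import (BioclimStack, GeoTransform, SampleSet, save_model,
                 write_raster, write_samples)
from .membership import MembershipFunction
from .reference import (BIOCLIM_CODES, PRECIPITATION_CODES, TEMPERATURE_CODES,
                        default_variable_ranges, planted_membership_functions)
from .scenarios import (EMISSIONS, GCMS, PERIODS, ScenarioResult, ScenarioSpec,
                        project)
from .suitability import SuitabilityModel
from .weighting import WeightVector

logger = logging.getLogger("habisuit")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the study design: a mountain-belt-sized window of
    ~1 km-scale cells, 19 variables with ranges centred on the reference
    optima, ~300 samples, content noise of 0.05 on the membership scale
    and a maximum observed content of 1.948 %.
    """

    shape: tuple[int, int] = (48, 64)
    cell_size: float = 0.05
    origin: tuple[float, float] = (104.0, 35.0)  # west edge, north edge
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=default_variable_ranges)
    functions: Mapping[str, MembershipFunction] = field(
        default_factory=planted_membership_functions)
    weights: Mapping[str, float] | None = None  # None: uniform
    cross_corr: float = 0.9
    smoothness: int = 3
    content_noise_sd: float = 0.05
    c_max: float = 1.948
    nodata_fraction: float = 0.02
    bio7_identity: bool = True
    seed: int = 0

    def __post_init__(self):
        nrows, ncols = self.shape
        if nrows < 4 or ncols < 4:
            raise ValidationError("grid must be at least 4 x 4")
        if self.cell_size <= 0:
            raise ValidationError("cell size must be positive")
        if not (0.0 <= self.cross_corr <= 1.0):
            raise ValidationError("cross_corr must lie in [0, 1]")
        if self.content_noise_sd < 0:
            raise ValidationError("content noise sd must be nonnegative")
        if self.c_max <= 0:
            raise ValidationError("c_max must be positive")
        if not (0.0 <= self.nodata_fraction < 0.5):
            raise ValidationError("nodata_fraction must lie in [0, 0.5)")
        for code, (lo, hi) in self.ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
                raise ValidationError(f"invalid range for {code}: ({lo}, {hi})")


def _smooth_field(rng: np.random.Generator, shape, smoothness: int) -> np.ndarray:
    """White noise smoothed by a moving average, min-max scaled to [0, 1]."""
    raw = rng.standard_normal(shape)
    if smoothness > 0:
        raw = uniform_filter(raw, size=2 * smoothness + 1, mode="nearest")
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)


def _latent_gradient(rng: np.random.Generator, shape, smoothness: int):
    """Affine trend in a random direction plus smoothed noise, in [0, 1]."""
    nrows, ncols = shape
    theta = rng.uniform(0, 2 * np.pi)
    rr, cc = np.meshgrid(np.linspace(0, 1, nrows), np.linspace(0, 1, ncols),
                         indexing="ij")
    trend = np.cos(theta) * cc + np.sin(theta) * rr
    trend = (trend - trend.min()) / max(trend.max() - trend.min(), 1e-12)
    u = 0.5 * trend + 0.5 * _smooth_field(rng, shape, smoothness)
    lo, hi = u.min(), u.max()
    return (u - lo) / (hi - lo)


def gen_stack(cfg: SyntheticConfig, seed: int | None = None) -> BioclimStack:
    """Generate a co-registered 19-layer synthetic bioclim stack.

    Deterministic per seed (``cfg.seed`` unless overridden). Each layer
    is an affine rescaling of ``cross_corr * u + (1 - cross_corr) * eta_j``
    into its configured range, with ``u`` the shared latent gradient and
    ``eta_j`` variable-specific smoothed noise; Bio7 is computed as
    Bio5 − Bio6 when the identity is enabled.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    u = _latent_gradient(rng, cfg.shape, cfg.smoothness)
    rho = cfg.cross_corr

    layers: dict[str, np.ndarray] = {}
    for code in BIOCLIM_CODES:
        if code == "Bio7" and cfg.bio7_identity:
            continue
        if code not in cfg.ranges:
            raise ValidationError(f"no range configured for {code}")
        eta = _smooth_field(rng, cfg.shape, cfg.smoothness)
        v = rho * u + (1.0 - rho) * eta
        lo, hi = cfg.ranges[code]
        layers[code] = lo + (hi - lo) * v
    if cfg.bio7_identity:
        layers["Bio7"] = layers["Bio5"] - layers["Bio6"]
    layers = {code: layers[code] for code in BIOCLIM_CODES}

    mask = np.zeros(cfg.shape, dtype=bool)
    if cfg.nodata_fraction > 0:
        nrows, ncols = cfg.shape
        n_bad = int(round(cfg.nodata_fraction * nrows * ncols))
        if n_bad:
            # a contiguous corner block, as real windows have clipped edges
            k = max(1, int(np.sqrt(n_bad)))
            mask[:k, : int(np.ceil(n_bad / k))] = True

    x0, y0 = cfg.origin
    transform = GeoTransform(x0=x0, y0=y0, dx=cfg.cell_size, dy=cfg.cell_size)
    return BioclimStack(layers=layers, transform=transform, nodata_mask=mask)


def planted_model(cfg: SyntheticConfig,
                  stack: BioclimStack | None = None) -> SuitabilityModel:
    """The true suitability model behind a synthetic landscape.

    With ``cfg.weights`` unset the planted weights are uniform — the
    fixed point of the fit→weight loop (see the module docstring), and
    the only planting the entropy method can be expected to recover
    from aggregate content.
    """
    functions = dict(cfg.functions)
    if cfg.weights is not None:
        weights = WeightVector(dict(cfg.weights))
    else:
        weights = WeightVector({c: 1.0 / len(functions) for c in functions})
    return SuitabilityModel(functions=functions, weights=weights,
                            c_max=cfg.c_max)


_ANCHOR_TOL = 0.99
_ANCHOR_ATTEMPTS = 100


def gen_samples(stack: BioclimStack, true_model: SuitabilityModel, n: int,
                cfg: SyntheticConfig, seed: int | None = None) -> SampleSet:
    """Draw noisy samples at random valid cells.

    Content of site *i* is ``clip(y_i + eps_i, 0, 1) * c_max`` with the
    true index ``y_i`` at the site's cell and Gaussian noise on the
    membership scale. Sites are jittered uniformly within their cell.
    The draw is repeated (bounded) until at least one content lies within
    1 % of ``c_max``; as a last resort one site is moved to the cell of
    maximum true suitability (logged).
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    valid_flat = np.flatnonzero(~stack.nodata_mask.ravel())
    if n < 4:
        raise ValidationError("need at least 4 samples")
    if n > valid_flat.size:
        raise ValidationError(
            f"cannot place {n} samples on {valid_flat.size} valid cells")

    nrows, ncols = stack.shape
    codes = true_model.codes
    y_grid = np.full(stack.shape, -np.inf)
    valid = ~stack.nodata_mask
    vals = np.column_stack([stack.layer(c)[valid] for c in codes])
    y_grid[valid] = true_model.index_of(vals)

    def draw():
        cells = rng.choice(valid_flat, size=n, replace=False)
        rows, cols = np.unravel_index(cells, stack.shape)
        jit_x = rng.uniform(0.02, 0.98, size=n)
        jit_y = rng.uniform(0.02, 0.98, size=n)
        lons = stack.transform.x0 + (cols + jit_x) * stack.transform.dx
        lats = stack.transform.y0 - (rows + jit_y) * stack.transform.dy
        y = y_grid[rows, cols]
        eps = rng.normal(0.0, cfg.content_noise_sd, size=n)
        content = np.clip(y + eps, 0.0, 1.0) * cfg.c_max
        return lons, lats, content

    for attempt in range(_ANCHOR_ATTEMPTS):
        lons, lats, content = draw()
        if cfg.content_noise_sd == 0 or content.max() >= _ANCHOR_TOL * cfg.c_max:
            break
    else:
        lons, lats, content = draw()
        best = np.argmax(y_grid)
        r, c = np.unravel_index(best, stack.shape)
        lon, lat = stack.transform.cell_center(r, c)
        lons[0], lats[0] = lon, lat
        eps = abs(rng.normal(0.0, cfg.content_noise_sd))
        content[0] = np.clip(y_grid[r, c] + eps, 0.0, 1.0) * cfg.c_max
        logger.warning("gen_samples: anchor guard forced a site onto the "
                       "maximum-suitability cell after %d attempts",
                       _ANCHOR_ATTEMPTS)

    import pandas as pd

    table = pd.DataFrame({
        "site_id": [f"S{i + 1:04d}" for i in range(n)],
        "lon": lons,
        "lat": lats,
        "content": content,
    })
    return SampleSet(table)


def gen_future(stack: BioclimStack,
               temp_deltas: Mapping[str, float] | None = None,
               precip_factors: Mapping[str, float] | None = None,
               recompute_bio7: bool = True) -> BioclimStack:
    """Delta-method future stack: additive temperature shifts,
    multiplicative precipitation factors; mask and geotransform unchanged.

    Codes must belong to the known temperature / precipitation sets.
    With ``recompute_bio7`` the Bio7 = Bio5 − Bio6 identity is restored
    after shifting (a no-op under uniform warming).
    """
    temp_deltas = dict(temp_deltas or {})
    precip_factors = dict(precip_factors or {})
    bad_t = set(temp_deltas) - TEMPERATURE_CODES
    if bad_t:
        raise ValidationError(
            f"additive deltas only apply to temperature layers; got {sorted(bad_t)}")
    bad_p = set(precip_factors) - PRECIPITATION_CODES
    if bad_p:
        raise ValidationError(
            f"multiplicative factors only apply to precipitation layers; "
            f"got {sorted(bad_p)}")

    layers = {}
    for code, arr in stack.layers.items():
        out = arr.copy()
        if code in temp_deltas:
            out = out + temp_deltas[code]
        if code in precip_factors:
            out = out * precip_factors[code]
        layers[code] = out
    if recompute_bio7 and {"Bio5", "Bio6", "Bio7"} <= set(layers):
        layers["Bio7"] = layers["Bio5"] - layers["Bio6"]
    return stack.with_layers(layers)


def uniform_warming(stack: BioclimStack, delta_t: float,
                    precip_factor: float = 1.0) -> BioclimStack:
    """Shift every absolute-temperature layer by ``delta_t`` °C and scale
    every precipitation-amount layer by ``precip_factor``."""
    return gen_future(
        stack,
        temp_deltas={c: delta_t for c in TEMPERATURE_CODES if c in stack.layers},
        precip_factors={c: precip_factor for c in PRECIPITATION_CODES
                        if c in stack.layers},
    )


# ---------------------------------------------------------------------------
# scenario suite
# ---------------------------------------------------------------------------

# warming (°C) by period, scaled per emission storyline, offset per GCM;
# precipitation scales with warming (wetter, further off the optima)
_PERIOD_WARMING = {"2020s": 0.8, "2050s": 1.8, "2080s": 3.2}
_EMISSION_FACTOR = {"A1B": 1.15, "A2": 1.25, "B1": 0.8}
_GCM_OFFSET = {"BC": -0.2, "CC": 0.0, "MI": 0.2}
_PRECIP_PER_DEGREE = 0.04


def scenario_deltas(spec: ScenarioSpec) -> tuple[float, float]:
    """(temperature delta °C, precipitation factor) for one scenario."""
    dt = (_PERIOD_WARMING[spec.period] * _EMISSION_FACTOR[spec.emission]
          + _GCM_OFFSET[spec.gcm])
    return dt, 1.0 + _PRECIP_PER_DEGREE * dt


def all_scenario_specs() -> list[ScenarioSpec]:
    return [ScenarioSpec(e, g, p)
            for e in EMISSIONS for g in GCMS for p in PERIODS]


def simulate_scenarios(model: SuitabilityModel, present: BioclimStack,
                       specs: Sequence[ScenarioSpec] | None = None
                       ) -> list[ScenarioResult]:
    """Project the model over a suite of delta-perturbed future stacks."""
    specs = list(specs) if specs is not None else all_scenario_specs()
    results = []
    for spec in specs:
        dt, pf = scenario_deltas(spec)
        future = uniform_warming(present, dt, pf)
        results.append(project(model, future, spec))
    return results


# ---------------------------------------------------------------------------
# ready-to-run workspace
# ---------------------------------------------------------------------------

def write_workspace(out_dir, cfg: SyntheticConfig | None = None,
                    n_samples: int = 300) -> dict[str, Path]:
    """Emit a complete synthetic workspace: a stack directory of ASCII
    grids, a sample CSV, the planted truth model (JSON) and a scenario
    table (YAML). Returns the paths written."""
    cfg = cfg or SyntheticConfig()
    out_dir = Path(out_dir)
    stack_dir = out_dir / "stack"
    stack_dir.mkdir(parents=True, exist_ok=True)

    stack = gen_stack(cfg)
    truth = planted_model(cfg, stack)
    samples = gen_samples(stack, truth, n_samples, cfg)

    paths: dict[str, Path] = {}
    for code in stack.codes:
        p = stack_dir / f"{code.lower()}.asc"
        write_raster(p, stack.layer(code), stack.transform, stack.nodata_mask)
        paths[code] = p
    paths["samples"] = write_samples(samples, out_dir / "samples.csv")
    paths["truth"] = save_model(truth, out_dir / "truth.json", seed=cfg.seed)

    scenario_table = {
        spec.label: {
            "emission": spec.emission, "gcm": spec.gcm, "period": spec.period,
            "temp_delta": round(scenario_deltas(spec)[0], 6),
            "precip_factor": round(scenario_deltas(spec)[1], 6),
        }
        for spec in all_scenario_specs()
    }
    scen_path = out_dir / "scenarios.yaml"
    scen_path.write_text(yaml.safe_dump(scenario_table, sort_keys=True))
    paths["scenarios"] = scen_path
    logger.info("synthetic workspace written to %s", out_dir)
    return paths
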