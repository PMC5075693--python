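"""Shared fixtures: one canonical synthetic study, computed once per session.

The "study" fixtures reproduce the default conditions end to end —
default landscape (48 x 64 cells, 19 co-varying layers), 300 samples
with content noise 0.05 on the membership scale, 75/25 split — all under
seed 0, so every test that needs a fitted pipeline reuses the same one.
"""

import numpy as np
import pytest

import habisuit as hs

STUDY_SEED = 0
N_SAMPLES = 300


@pytest.fixture(scope="session")
def study_cfg() -> hs.SyntheticConfig:
    return hs.SyntheticConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_stack(study_cfg):
    return hs.gen_stack(study_cfg)


@pytest.fixture(scope="session")
def study_truth(study_cfg, study_stack):
    return hs.planted_model(study_cfg, study_stack)


@pytest.fixture(scope="session")
def study_samples(study_cfg, study_stack, study_truth):
    return hs.gen_samples(study_stack, study_truth, N_SAMPLES, study_cfg)


@pytest.fixture(scope="session")
def study_pipeline(study_stack, study_samples):
    return hs.fit_suitability_model(study_stack, study_samples, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_true_index(study_stack, study_truth):
    """True suitability index per grid cell (NaN on nodata)."""
    grid = np.full(study_stack.shape, np.nan)
    valid = ~study_stack.nodata_mask
    vals = np.column_stack(
        [study_stack.layer(c)[valid] for c in study_truth.codes])
    grid[valid] = study_truth.index_of(vals)
    return grid


@pytest.fixture()
def tiny_transform():
    return hs.GeoTransform(x0=100.0, y0=40.0, dx=0.5, dy=0.5)


@pytest.fixture()
def tiny_stack(tiny_transform):
    """A 2-variable, 2x2 stack with hand-set values for exact checks."""
    layers = {
        "Bio1": np.array([[10.3, 5.0], [0.0, 20.0]]),
        "Bio12": np.array([[853.0, 400.0], [600.0, 1200.0]]),
    }
    mask = np.zeros((2, 2), dtype=bool)
    return hs.BioclimStack(layers=layers, transform=tiny_transform,
                           nodata_mask=mask)
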