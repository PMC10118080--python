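import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from oilmark.io_formats import read_marker_library
from oilmark.marker_discovery import fit_class_model
from oilmark.pipeline import RunConfig, build_matrix
from oilmark.synthetic_data import SimulationDesign, simulate_study

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def library():
    return read_marker_library()


@pytest.fixture(scope="session")
def noise_free_design():
    return SimulationDesign(seed=7).noise_free()


@pytest.fixture(scope="session")
def default_design():
    return SimulationDesign(seed=7)


def _study(design):
    cfg = RunConfig(seed=design.seed, design=design)
    samples, truth = simulate_study(design)
    matrix = build_matrix(samples, cfg)
    return samples, truth, matrix, cfg


@pytest.fixture(scope="session")
def noise_free_study(noise_free_design):
    """samples, ground truth, filtered matrix, config — zero-noise study."""
    return _study(noise_free_design)


@pytest.fixture(scope="session")
def default_study(default_design):
    """samples, ground truth, filtered matrix, config — default-noise study."""
    return _study(default_design)


@pytest.fixture(scope="session")
def default_model(default_study):
    _, _, matrix, _ = default_study
    model, oil_cols = fit_class_model(matrix, cv_folds=7)
    return model, oil_cols


@pytest.fixture
def rng():
    return np.random.default_rng(20230420)
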