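"""Shared fixtures.

The expensive artefacts (full 300-node training builds, fitted PCA/SVR
models, the trained CNN) are session-scoped so the whole suite pays for
each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from beamtune.config import RunConfig
from beamtune.params import DEFAULT_TEST_POOL, BeamParameters, sample_test_tuples
from beamtune.pipeline import (
    build_training_data,
    fit_pca_models,
    profile_sets_for_tuples,
)
from beamtune.surrogate import generate_dose3d
from beamtune.svr import train_svr


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    """Default study conditions: full grid, six profiles, 1 mm step, noise on."""
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def training_data(run_config):
    return build_training_data(run_config)


@pytest.fixture(scope="session")
def pca_models(training_data):
    return fit_pca_models(training_data, k=3)


@pytest.fixture(scope="session")
def svr_bundle(pca_models, training_data, run_config):
    return train_svr(pca_models, training_data.grid, seed=run_config.seed)


@pytest.fixture(scope="session")
def test_tuples(run_config):
    return sample_test_tuples(DEFAULT_TEST_POOL(n_samples=25, seed=run_config.seed))


@pytest.fixture(scope="session")
def test_sets(run_config, test_tuples):
    return profile_sets_for_tuples(run_config, test_tuples)


# -- reduced-resolution conditions for the deep model (2 mm sampling keeps
#    300 epochs of CNN training affordable on one CPU) ----------------------


@pytest.fixture(scope="session")
def dl_config() -> RunConfig:
    return RunConfig(seed=0, step=0.2)


@pytest.fixture(scope="session")
def dl_training(dl_config):
    return build_training_data(dl_config)


@pytest.fixture(scope="session")
def dl_pca_models(dl_training):
    return fit_pca_models(dl_training, k=3)


@pytest.fixture(scope="session")
def dl_svr_bundle(dl_pca_models, dl_training, dl_config):
    return train_svr(dl_pca_models, dl_training.grid, seed=dl_config.seed)


@pytest.fixture(scope="session")
def dl_model(dl_training, dl_config):
    from beamtune.deep import train_deep

    return train_deep(
        dl_training.profile_sets,
        dl_training.targets(),
        dl_training.grid.hypercube,
        seed=dl_config.seed,
    )


@pytest.fixture(scope="session")
def dl_test_sets(dl_config, test_tuples):
    return profile_sets_for_tuples(dl_config, test_tuples)


# -- small one-off objects -------------------------------------------------


@pytest.fixture(scope="session")
def example_params() -> BeamParameters:
    return BeamParameters(E=6.0, sigma_E=0.5, s=0.2, alpha=1.0)


@pytest.fixture(scope="session")
def noiseless_dose10(example_params):
    return generate_dose3d(example_params, 10.0, noise=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
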