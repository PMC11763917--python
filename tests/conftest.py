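"""Shared fixtures: small synthetic cohorts and desk-scale trained models.

All fixtures are deterministic; the heavier trained-model fixtures are
session-scoped so multiple test modules can share one training run.
"""

import numpy as np
import pytest

from arrowtime.core_data import Cohort, SubjectTimeSeries
from arrowtime.model import ModelConfig, init_model
from arrowtime.synthetic import ChirpParams, generate_chirp_cohort
from arrowtime.training import TrainConfig, build_tr_dataset, train


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cohort(rng):
    """Three labeled subjects, 6 time points x 3 components."""
    subjects = [
        SubjectTimeSeries(f"s{i}", rng.normal(size=(6, 3)), label=i % 2)
        for i in range(3)
    ]
    return Cohort("tiny", subjects)


@pytest.fixture(scope="session")
def small_chirp_cohort():
    """32 chirp subjects at a scale where the arrow of time is learnable."""
    params = ChirpParams(n_components=6, n_timepoints=64, noise_sd=0.1, seed=7)
    return generate_chirp_cohort(32, params)


@pytest.fixture(scope="session")
def small_model_config():
    return ModelConfig(
        input_size=6, lstm_hidden=32, attention_hidden=32, decoder_hidden=8,
        dropout_rate=0.2, seed=7,
    )


@pytest.fixture(scope="session")
def briefly_trained_model(small_chirp_cohort, small_model_config):
    """A partially trained model whose output varies smoothly along IG paths.

    30 epochs leaves the classifier clearly better than its initialization
    but far from the saturated regime, which is what the integrated-gradients
    numerics tests need.
    """
    data = build_tr_dataset(small_chirp_cohort)
    cfg = TrainConfig(seed=7, max_epochs=30, early_stop_patience=1000)
    fitted, _ = train(init_model(small_model_config), data, cfg)
    return fitted
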