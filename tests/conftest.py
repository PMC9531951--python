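import numpy as np
import pytest

from smfsid import synthetic as syn
from smfsid.preprocess import estimate_batch_noise, filter_block1
from smfsid.quality_score import score_traces


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def templates():
    return syn.example_templates(3)


@pytest.fixture(scope="session")
def clean_sim_config():
    return syn.SimulationConfig(seed=42, premature_detach_fraction=0.0)


@pytest.fixture(scope="session")
def clean_batch(templates, clean_sim_config):
    """A 60-curve 1:1:1 mixture with labels, shared across tests."""
    curves, labels = syn.simulate_dataset(templates, [1, 1, 1], 60, clean_sim_config)
    return curves, labels


@pytest.fixture(scope="session")
def scored_batch(clean_batch):
    """Preprocessed + quality-scored traces of the clean batch."""
    curves, labels = clean_batch
    sigma = estimate_batch_noise(curves)
    traces, report = filter_block1(curves, sigma)
    scored, rejected = score_traces(traces)
    return scored, labels, sigma
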