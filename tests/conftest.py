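import numpy as np
import pytest

import immunogate as ig
from immunogate import pipeline

# Desk-scale clustering subsample used throughout the suite (density
# estimation runs on <= this many events; all events are still assigned)
TEST_CAP = 10_000


@pytest.fixture(scope="session")
def panel():
    return ig.default_panel()


@pytest.fixture(scope="session")
def normal_case(panel):
    """One NORMAL case at 8,000 events/tube with default artifact rates."""
    scenario = ig.make_scenario("NORMAL", seed=11, n_events=8000)
    samples, truth = ig.make_case(scenario, panel)
    return samples, truth


@pytest.fixture(scope="session")
def small_models(panel):
    """Forests trained on a small labeled batch — enough for lineage
    separation on synthetic data, cheap enough for unit tests."""
    stores = pipeline.build_training_stores(
        8, base_seed=42, panel=panel, n_events=6000, downsample_cap=TEST_CAP)
    return pipeline.train_models(stores, seed=42)


@pytest.fixture(scope="session")
def full_models(panel):
    """Forests trained on the full 60-case labeled batch (the training-set
    size of the validation design)."""
    stores = pipeline.build_training_stores(
        60, base_seed=0, panel=panel, n_events=20_000,
        downsample_cap=TEST_CAP)
    return pipeline.train_models(stores, seed=0)


@pytest.fixture(scope="session")
def clean_alps_t(panel, normal_case):
    """Pre-gated, transformed ALPS-T tube of the NORMAL case."""
    samples, truth = normal_case
    sample = samples["ALPS-T"]
    tube = ig.match_tube(sample, panel)
    clean = ig.pregate(sample)
    clean.sample = ig.apply_transform(clean.sample)
    return tube, clean, truth


def rng(seed: int) -> np.random.RandomState:
    return np.random.RandomState(seed)
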