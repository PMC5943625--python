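"""Shared fixtures: one trained walk model, one simulated day, one
pipeline run — session-scoped so the expensive pieces are computed once."""

import numpy as np
import pytest

from onoff.config import PipelineConfig
from onoff.gait_svm import train_walk_model
from onoff.pipeline import run_pipeline
from onoff.signals import feature_matrix
from onoff.synthetic import SimProfile, segment_corpus, simulate_recording

CORPUS_SEED = 11
MODEL_SEED = 7
DAY_SEED = 3


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def corpus(config):
    """Balanced labelled segment corpus (walk/rest/dysk/transition), n=2000."""
    segs, labels, is_walking = segment_corpus(SimProfile(seed=DAY_SEED), 2000, CORPUS_SEED)
    X = feature_matrix(segs, config.featbank)
    return segs, labels, is_walking, X


@pytest.fixture(scope="session")
def walk_model(config, corpus):
    _, _, is_walking, X = corpus
    return train_walk_model(X, is_walking, seed=MODEL_SEED, config=config)


@pytest.fixture(scope="session")
def sim_day():
    """Default 8-h simulated day with ground truth and event log."""
    profile = SimProfile(seed=DAY_SEED)
    rec, truth, events = simulate_recording(profile)
    return profile, rec, truth, events


@pytest.fixture(scope="session")
def pipeline_states(sim_day, walk_model, config):
    _, rec, _, _ = sim_day
    return run_pipeline(rec, walk_model, config)
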