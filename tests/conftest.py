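"""Shared fixtures: one small simulated cohort reused across test modules."""

from __future__ import annotations

import logging

import numpy as np
import pytest

import facekin as fk
from facekin.preprocess import preprocess_sequence

# PCA floor warnings are expected at toy scale and would drown test logs
logging.getLogger("facekin.modeling").setLevel(logging.ERROR)

TOY_SEED = 42


@pytest.fixture(scope="session")
def toy_sim_config() -> fk.SimulationConfig:
    """20 subjects, 60 landmarks (20 signal), 900 frames, strong coupling."""
    return fk.SimulationConfig.toy(seed=TOY_SEED, coupling_strength=1.5)


@pytest.fixture(scope="session")
def toy_pipeline_config() -> fk.PipelineConfig:
    return fk.PipelineConfig.toy(pca_components=8, seed=TOY_SEED)


@pytest.fixture(scope="session")
def toy_cohort(toy_sim_config):
    """Raw (sequences, records, traits) for the toy cohort."""
    return fk.simulate_cohort(toy_sim_config)


@pytest.fixture(scope="session")
def toy_preprocessed(toy_cohort, toy_pipeline_config):
    """Preprocessed sequences plus their records (all toy captures survive)."""
    seqs, records, _ = toy_cohort
    kept = []
    for seq in seqs:
        out, report = preprocess_sequence(seq, toy_pipeline_config)
        assert not report.discarded
        kept.append(out)
    return kept, records


@pytest.fixture(scope="session")
def toy_features(toy_preprocessed, toy_pipeline_config):
    """Screening result and feature matrix for the toy cohort."""
    seqs, _ = toy_preprocessed
    screening = fk.screen_corpus(seqs, toy_pipeline_config.top_points)
    features = fk.extract_features(seqs, screening.selected, toy_pipeline_config)
    return screening, features


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
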