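"""Shared fixtures: tiny model configurations and synthetic recordings."""

import numpy as np
import pytest

import gyrosde as g
from gyrosde.generative import GenerativeConfig
from gyrosde.inference import TransformerConfig
from gyrosde.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_model_config():
    """Small but structurally complete model for fast tests."""
    return ModelConfig(
        T=30,
        generative=GenerativeConfig(drift_hidden=(16,), decoder_hidden=(16,)),
        transformer=TransformerConfig(n_layers=2, n_heads=1, embed_dim=16,
                                      max_len=31),
    )


@pytest.fixture
def walking_subject():
    return g.SubjectProfile("s1", phase_offsets=(0.3, 1.1, 2.2))


@pytest.fixture
def noiseless_subject():
    return g.SubjectProfile("s0", phase_offsets=(0.3, 1.1, 2.2),
                            noise_sd=0.0)


@pytest.fixture
def walking_recording(walking_subject):
    return g.generate_recording(g.archetype("walking"), walking_subject,
                                600, seed=0)


@pytest.fixture
def two_subject_recordings():
    subjects = g.draw_subjects(2, seed=3)
    return [g.generate_recording(g.archetype("walking"), s, 600, seed=i)
            for i, s in enumerate(subjects)]
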