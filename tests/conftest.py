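"""Shared fixtures: small deterministic lexica and studies."""

import warnings

import numpy as np
import pytest

from lexcat import GenerativeConfig
from lexcat.simulate import simulate_lexicon, simulate_stimuli, simulate_study

warnings.filterwarnings("ignore", message="singular fit")
warnings.filterwarnings("ignore", message="constant predictor")
warnings.filterwarnings("ignore", message="cutoff .* exceeds")


@pytest.fixture(scope="session")
def small_lexicon():
    cfg = GenerativeConfig(n_participants=2, n_trials_per_session=100,
                           lexicon_size=300, seed=12345)
    return simulate_lexicon(cfg, np.random.default_rng(12345))


@pytest.fixture(scope="session")
def small_stimuli(small_lexicon):
    return simulate_stimuli(small_lexicon, 200, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_study():
    """One-session study small enough for repeated mixed-model fits."""
    cfg = GenerativeConfig(n_participants=12, n_trials_per_session=160,
                           lexicon_size=400, seed=2024)
    return simulate_study(cfg, sessions=1)


@pytest.fixture(scope="session")
def two_session_study():
    cfg = GenerativeConfig(n_participants=16, n_trials_per_session=240,
                           n_sessions=2, lexicon_size=500, seed=77)
    return simulate_study(cfg)
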