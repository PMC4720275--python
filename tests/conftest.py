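"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

import tonocortex as tc
from tonocortex.protocol import StimulusType


@pytest.fixture(scope="session")
def small_protocol():
    """10 trials per type, default ISI — fast but structurally complete."""
    return tc.generate_protocol(n_per_type=10, seed=11)


@pytest.fixture(scope="session")
def effect_dataset():
    """16-channel dataset with a clear condition effect (40 trials/type)."""
    prot = tc.generate_protocol(n_per_type=40, seed=21)
    cfg = tc.SimConfig(n_channels=16, trials_per_condition=40,
                       noise_sd_uv=5.0, effect_scale=1.0, seed=22)
    return tc.simulate_epochs(cfg, prot)


@pytest.fixture(scope="session")
def null_dataset():
    """Null dataset: identical templates across all conditions."""
    prot = tc.generate_protocol(n_per_type=40, seed=31)
    cfg = tc.SimConfig(n_channels=16, trials_per_condition=40,
                       noise_sd_uv=5.0, effect_scale=0.0, seed=32)
    return tc.simulate_epochs(cfg, prot)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def a_condition():
    return StimulusType(1000, "binaural")
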