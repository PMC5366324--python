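import dataclasses

import numpy as np
import pytest

from eegnaming import generate_signature, generate_participant
from eegnaming.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def small_planted_participant():
    """Three short sessions with one strong effect at (Cz, 10-13 Hz)."""
    sig = dataclasses.replace(
        generate_signature(1),
        effect_weights={("Cz", (10, 13)): 1.0},
        link_slope=2.0,
        amplitude_gain=0.6,
        effect_rms=6.0,
    )
    cfg = GeneratorConfig(trials_per_session=60, seed=11)
    return sig, cfg, generate_participant(sig, cfg, participant_id="planted")


@pytest.fixture(scope="session")
def tiny_session():
    """One 12-trial session for serialization and bookkeeping tests."""
    sig = generate_signature(3)
    cfg = GeneratorConfig(trials_per_session=12, seed=3)
    from eegnaming import generate_session

    return generate_session(sig, cfg, 1, participant_id="tiny")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
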