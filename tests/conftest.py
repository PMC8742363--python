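import numpy as np
import pytest

from gaitmetrics.segmentation import ActionLabel
from gaitmetrics.synthetic import (
    DEFAULT_SESSION_SCRIPT,
    ParticipantProfile,
    generate_jumping_jack,
    generate_session,
)


@pytest.fixture(scope="session")
def symmetric_profile() -> ParticipantProfile:
    """A perfectly symmetric, noise-free, phase-locked mover."""
    return ParticipantProfile(
        height=1.60,
        rl_amplitude_ratio=1.0,
        rl_lag=0.0,
        noise_sd=0.0,
        timing_jitter=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def symmetric_jj(symmetric_profile):
    """5 symmetric jumping-jack cycles with ground truth."""
    return generate_jumping_jack(symmetric_profile, n_cycles=5)


@pytest.fixture(scope="session")
def template_model():
    """Reference templates fitted from three training profiles."""
    from gaitmetrics.segmentation import fit_templates

    train = []
    for seed, h in [(1, 1.45), (2, 1.60), (3, 1.75)]:
        p = ParticipantProfile(
            height=h, seed=seed, noise_sd=0.003, timing_jitter=0.03,
            rl_amplitude_ratio=0.9, rl_lag=0.03,
        )
        train.append(generate_session(list(DEFAULT_SESSION_SCRIPT), p))
    return fit_templates(train)
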