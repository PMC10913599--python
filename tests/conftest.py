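import numpy as np
import pytest

from statedyn.synthetic import SyntheticSpec, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs():
    """Two tight, well-separated 2-D blobs of 10 points each."""
    gen = np.random.default_rng(7)
    a = np.array([10.0, 0.0]) + 0.05 * gen.standard_normal((10, 2))
    b = np.array([-10.0, 5.0]) + 0.05 * gen.standard_normal((10, 2))
    x = np.vstack([a, b])
    truth = np.array([0] * 10 + [1] * 10)
    return x, truth


@pytest.fixture
def small_study():
    """3 participants x 3 sessions with clear participant structure."""
    spec = SyntheticSpec(
        n_participants=4,
        n_sessions=4,
        t_volumes=150,
        n_rois=8,
        k_states=4,
        dwell_prob=0.6,
        participant_divergence=0.5,
        transition_jitter=0.2,
        noise_sd=0.3,
        seed=42,
    )
    return generate_study(spec)


@pytest.fixture
def null_study():
    """No participant-specific structure (divergence = jitter = 0)."""
    spec = SyntheticSpec(
        n_participants=3,
        n_sessions=3,
        t_volumes=150,
        n_rois=8,
        k_states=3,
        dwell_prob=0.5,
        participant_divergence=0.0,
        transition_jitter=0.0,
        noise_sd=0.3,
        seed=43,
    )
    return generate_study(spec)
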