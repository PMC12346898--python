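import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced 24-subject cohort shared by the heavier tests."""
    from lungsound.synth import CohortSpec, synthesize_cohort

    spec = CohortSpec(
        n_subjects=24,
        class_proportions=(1 / 3, 1 / 3, 1 / 3),
        seed=1234,
        snr_db=30.0,
        duration_s=6.0,
    )
    recordings, manifest = synthesize_cohort(spec)
    return spec, recordings, manifest


@pytest.fixture(scope="session")
def separability_cohort():
    """300 recordings at high SNR with strong class parameters."""
    from lungsound.synth import CohortSpec, synthesize_cohort

    spec = CohortSpec(
        n_subjects=300,
        class_proportions=(1 / 3, 1 / 3, 1 / 3),
        seed=77,
        snr_db=30.0,
    )
    recordings, _ = synthesize_cohort(spec)
    return recordings


@pytest.fixture()
def sine_signal():
    from lungsound.audio_io import AudioSignal

    fs = 4000
    t = np.arange(fs) / fs
    return AudioSignal(0.5 * np.sin(2 * np.pi * 440.0 * t), fs)
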