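import numpy as np
import pytest

from placebo_eeg.core import N_CHANNELS, SEGMENT_SAMPLES
from placebo_eeg.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects, 20-s sessions, no artifacts: fast shared raw material."""
    spec = CohortSpec(n_subjects=4, duration_s=20.0, artifact_rates={}, seed=7)
    recordings, subjects = generate_cohort(spec)
    return recordings, subjects


@pytest.fixture(scope="session")
def clean_recording(small_cohort):
    recordings, _ = small_cohort
    return recordings[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def segment(rng):
    """One band-limited [19 x 2000] segment with per-channel structure."""
    t = np.arange(SEGMENT_SAMPLES) / 125.0
    seg = np.empty((N_CHANNELS, SEGMENT_SAMPLES))
    for c in range(N_CHANNELS):
        seg[c] = (
            10.0 * np.sin(2 * np.pi * (6 + c) / 2.0 * t + c)
            + rng.standard_normal(SEGMENT_SAMPLES)
        )
    return seg
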