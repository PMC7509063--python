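import numpy as np
import pytest

from ssvepsync import (
    CVPlan,
    StimulusConfig,
    SyntheticSpec,
    simulate_dataset,
    twelve_class_keypad,
)
from ssvepsync.evaluation import run_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def keypad():
    return twelve_class_keypad()


@pytest.fixture(scope="session")
def small_stim():
    """Four well-separated stimulus frequencies for cheap unit tests."""
    return StimulusConfig((9.25, 10.75, 12.25, 13.75))


@pytest.fixture(scope="session")
def small_dataset(small_stim):
    """Tiny 3-subject cohort (4 classes, 6 trials, 4 channels, 2 s)."""
    spec = SyntheticSpec(
        n_subjects=3, n_trials_per_class=6, n_channels=4, duration_s=2.0,
        fs=128.0, subject_snr_db=(-8.0, -6.0, -4.0), lapse_rate=0.0, seed=7,
    )
    return simulate_dataset(spec, small_stim)


@pytest.fixture(scope="session")
def cohort(keypad):
    """The full-geometry synthetic study cohort (10 subjects, 12 classes)."""
    return simulate_dataset(SyntheticSpec(seed=42), keypad)


@pytest.fixture(scope="session")
def cohort_benchmark(cohort):
    """Cross-validated benchmark of all methods on the study cohort.

    Session-scoped: this is the expensive simulation shared by the
    method-ordering tests.
    """
    return run_benchmark(cohort, cv=CVPlan(n_folds=3, seed=1), n_donors=4)
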