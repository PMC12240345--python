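import numpy as np
import pytest

from acticomplex import ActivityTrace, healthy_template, patient_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_trace(rng):
    """A small nonnegative activity-like trace (5 s epochs, ~1 h)."""
    values = np.abs(rng.normal(0.03, 0.02, 720))
    return ActivityTrace(values=values, epoch_seconds=5.0, subject_id="unit")


@pytest.fixture(scope="session")
def mini_templates():
    """Short healthy/patient parameter sets for fast cohort runs (~8 h)."""
    n = 6000
    return (
        healthy_template(n_epochs=n),
        patient_template(n_epochs=n),
    )
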