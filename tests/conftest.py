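import numpy as np
import pytest

from svhdecay import CohortConfig, SettingSeries, sample_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default study-conformant synthetic cohort, shared across tests."""
    return sample_cohort(CohortConfig(seed=12345))


@pytest.fixture()
def clean_exponential_series():
    """Noiseless exponential series with known parameters."""
    t = np.linspace(4.0, 360.0, 20)
    y = 30.0 * np.exp(-0.01 * t) + 2.0
    return SettingSeries(subject_id="clean", run_id=1, times=t, svh=y), (30.0, 0.01, 2.0)
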