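import numpy as np
import pytest

from ppgstress import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort under the default rest/stress contrast."""
    return generate_cohort(SynthConfig(n_subjects=40, seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort for fast pipeline-level tests."""
    return generate_cohort(SynthConfig(n_subjects=6, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
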