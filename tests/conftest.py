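import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import connatlas as ca

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom5():
    """Small 5-subject phantom cohort (default study conditions)."""
    spec = ca.PhantomSpec(seed=7)
    return ca.make_phantom_dataset(spec, 5)


@pytest.fixture(scope="session")
def phantom20():
    """The 20-subject phantom used for pipeline-level checks."""
    spec = ca.PhantomSpec(seed=11)
    return ca.make_phantom_dataset(spec, 20)


@pytest.fixture(scope="session")
def atlas20(phantom20):
    """Atlas built end-to-end from the 20-subject phantom."""
    return ca.build_atlas_from_subjects(
        phantom20.tractograms, phantom20.parcellation
    )


@pytest.fixture(scope="session")
def atlas5(phantom5):
    return ca.build_atlas_from_subjects(
        phantom5.tractograms, phantom5.parcellation
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
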