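import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lkbntcp as lk

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def sef_params():
    """The SEF-fitted dose-response: n=1, m=0.18, TD50=43.6 Gy."""
    return lk.LKBParameters(n=1.0, m=0.18, td50=43.6)


@pytest.fixture
def qol_params():
    """The QoL-fitted dose-response: n=1, m=0.11, TD50=44.1 Gy."""
    return lk.LKBParameters(n=1.0, m=0.11, td50=44.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_curve(rng, n_bins=None):
    """A random valid differential DVH with positive, distinct doses."""
    n_bins = n_bins or int(rng.integers(1, 40))
    doses = np.sort(rng.uniform(0.5, 80.0, size=n_bins))
    doses = np.unique(doses)
    volumes = rng.dirichlet(np.ones(doses.size))
    return lk.DVHCurve.differential("r", doses, volumes)
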