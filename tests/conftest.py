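import numpy as np
import pytest
from hypothesis import settings

import expvat as ev

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_params():
    return ev.SimParams(noise_cv=0.0, seed=3)


@pytest.fixture(scope="session")
def noise_free_test(noise_free_params):
    return ev.simulate_subject(noise_free_params)


@pytest.fixture(scope="session")
def default_test():
    """One healthy-like noisy subject, fixed seed."""
    return ev.simulate_subject(ev.SimParams(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects spanning the default threshold range."""
    return ev.simulate_cohort(20, seed=42)


def exact_exponential(a=1.0015, b=300.0, lo=500.0, hi=2000.0, step=50.0):
    """Noise-free y = b*a**x on an evenly spaced VO2 grid."""
    x = np.arange(lo, hi + step / 2, step)
    return x, b * a ** x
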