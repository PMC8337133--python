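import numpy as np
import pytest

from fsvmsr import generate_blobs, generate_cohort, default_cohort_spec


@pytest.fixture(scope="session")
def separable_blobs():
    """Two well-separated Gaussian classes in 3-D."""
    centers = np.array([[3.0, 3.0, 3.0], [-3.0, -3.0, -3.0]])
    return generate_blobs((20, 12), centers, sd=0.5, seed=42)


@pytest.fixture(scope="session")
def three_class_blobs():
    centers = np.array([[4.0, 0.0], [-4.0, 4.0], [-4.0, -4.0]])
    return generate_blobs((15, 12, 9), centers, sd=0.6, seed=7)


@pytest.fixture(scope="session")
def table1_cohort():
    """Default synthetic cohort with the study's dimensions (59 x 29)."""
    return generate_cohort(default_cohort_spec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
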