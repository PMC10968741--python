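import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ivimsim as iv

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme():
    return iv.default_acquisition_scheme()


@pytest.fixture(scope="session")
def ground_truth():
    """The reference simulation's grey-matter-like ground truth."""
    return iv.IVIMParameters(s0=1.0, f=0.12, d_star=0.01, d=0.001)


@pytest.fixture(scope="session")
def clean_signal(ground_truth, scheme):
    return iv.ivim_signal(ground_truth, scheme)


@pytest.fixture(scope="session")
def small_phantom():
    """A small noised phantom shared by volume-level tests."""
    spec = iv.PhantomSpec(shape=(16, 16, 8), snr=20.0, seed=5)
    volume, labels = iv.make_phantom(spec)
    return spec, volume, labels


def one_log_step(axis: iv.GridAxis) -> float:
    """Multiplicative width of one step of a log-spaced grid axis."""
    return (axis.stop / axis.start) ** (1.0 / (axis.count - 1))


def one_linear_step(axis: iv.GridAxis) -> float:
    return (axis.stop - axis.start) / (axis.count - 1)
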