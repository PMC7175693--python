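import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import segdp as sd

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def gaussian():
    return sd.GaussianMeanCost()


@pytest.fixture
def poisson():
    return sd.PoissonMeanCost()


@pytest.fixture
def toy_step():
    """The six-point step signal (0,0,0,10,10,10): one clean change at t=3."""
    return sd.TimeSeries.from_values([0, 0, 0, 10, 10, 10])


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_series(rng, n, n_changes=0, shift=3.0):
    """A Gaussian series with optional evenly spaced mean shifts."""
    y = rng.normal(size=n)
    if n_changes:
        cps = np.linspace(0, n, n_changes + 2)[1:-1].astype(int)
        for i, cp in enumerate(cps):
            y[cp:] += shift * (1 if i % 2 == 0 else -1)
    return sd.TimeSeries.from_values(y)
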