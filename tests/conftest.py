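import numpy as np
import pytest

from dpmost.model import LongitudinalDataset, ModelParamsM2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, J=3, B=2, h=2):
    """Small random dataset + valid random parameter state."""
    times = [np.sort(rng.uniform(0, 10, size=h)) for _ in range(J)]
    values = [rng.normal(1.0, 0.8, size=(B, h)) for _ in range(J)]
    ds = LongitudinalDataset([f"s{j}" for j in range(J)], times, values,
                             [f"b{i}" for i in range(B)])
    params = ModelParamsM2(
        midpoint=rng.normal(5, 2, size=(B, 3)),
        growth_rate=rng.uniform(0.2, 1.5, size=(B, 3)),
        supremum=rng.uniform(0.5, 3.0, size=(B, 3)),
        sigma=rng.uniform(0.3, 1.2, size=B),
        xi1=rng.uniform(0.05, 0.95, size=B),
        tau=rng.normal(0, 2, size=J),
        pi1=rng.uniform(0.05, 0.95, size=J),
    )
    return ds, params


@pytest.fixture
def small_instance(rng):
    return random_instance(rng)
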