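import numpy as np
import pytest

from bpeec import BPEECParams, SeriesControl, normalizing_constant


@pytest.fixture(scope="session")
def dependent_params():
    """A parameter triple with genuine negative dependence."""
    return BPEECParams(-1.0, 1.0, -0.5)


@pytest.fixture(scope="session")
def independent_params():
    """alpha3 = 0: the joint factorizes exactly."""
    return BPEECParams(-np.log(2.0), 1.0, 0.0)


@pytest.fixture(scope="session")
def grid_params():
    """The 27-point validity grid used by the normalization properties."""
    return [
        BPEECParams(a1, a2, a3)
        for a1 in (-0.25, -1.0, -2.0)
        for a2 in (0.5, 1.0, 2.0)
        for a3 in (0.0, -0.5, -2.0)
    ]


def naive_normalizing_sum(p: BPEECParams, terms: int = 100_000) -> float:
    """Independent oracle: plain partial summation, no tail bound."""
    x = np.arange(terms, dtype=float)
    return float(np.sum(np.exp(p.alpha1 * (x + 1)) / (p.alpha2 - p.alpha3 * (x + 1))))


@pytest.fixture(scope="session")
def naive_oracle():
    return naive_normalizing_sum
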