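import numpy as np
import pytest

from cytobundle import DimensionlessParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def dashed_line_point():
    """The experimentally motivated actomyosin point at L_t = 1."""
    return DimensionlessParams(vt_t=2.0, tauc_t=0.2, L_t=1.0)


@pytest.fixture
def coexistence_point():
    """A point inside the bistable window of the dashed-line sweep."""
    return DimensionlessParams(vt_t=2.0, tauc_t=0.2, L_t=1.2)


def random_params(rng, n):
    """Seeded parameter sample spanning all three velocity regimes."""
    draws = rng.uniform([0.2, 0.1, 0.5], [3.0, 2.0, 5.0], size=(n, 3))
    return [DimensionlessParams(*row) for row in draws]
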