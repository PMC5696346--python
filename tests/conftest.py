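import numpy as np
import pytest

from mobisim import SpatialDomain, generate_synthetic_population


@pytest.fixture
def two_loc_domain():
    """Two locations with populations 5 and 10."""
    return SpatialDomain([0.0, 3.0], [0.0, 0.0], [5, 10])


@pytest.fixture
def triangle_domain():
    """Equilateral triangle, equal populations."""
    return SpatialDomain([0.0, 1.0, 0.5], [0.0, 0.0, np.sqrt(3) / 2], [4, 4, 4])


@pytest.fixture
def line4_domain():
    """Four collinear locations with populations 1..4."""
    return SpatialDomain([0.0, 1.0, 2.0, 3.0], [0.0] * 4, [1, 2, 3, 4])


@pytest.fixture
def random_domain():
    """20 random locations with heterogeneous populations."""
    rng = np.random.default_rng(12345)
    xy = rng.uniform(0, 50, size=(20, 2))
    m = rng.integers(1, 500, size=20)
    return SpatialDomain(xy[:, 0], xy[:, 1], m)


@pytest.fixture
def small_city_domain():
    """50-location Zipf-population domain for simulation tests."""
    return generate_synthetic_population(50, zipf_exponent=1.0, extent=100.0, seed=3)


def brute_force_W(domain):
    """Independent O(N^3) oracle: re-scan all locations for every (j, i)."""
    N = domain.N
    W = np.zeros((N, N), dtype=np.int64)
    for j in range(N):
        for i in range(N):
            d_ji = np.hypot(domain.x[i] - domain.x[j], domain.y[i] - domain.y[j])
            for k in range(N):
                d_jk = np.hypot(domain.x[k] - domain.x[j], domain.y[k] - domain.y[j])
                if d_jk <= d_ji * (1 + 1e-9) + 1e-12:
                    W[j, i] += domain.m[k]
    return W
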