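import numpy as np
import pytest

from organoise import CountSample, RateConstants


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def poisson_rates():
    """Immigration-death (Golgi-like) parameterization with mean 2."""
    return RateConstants(k_denovo=2.0, k_fission=0.0, k_fusion=0.0, gamma=1.0)


@pytest.fixture
def fission_fusion_rates():
    """Vacuole-like parameterization with mean-field mean 2.1."""
    return RateConstants(k_denovo=0.0, k_fission=1.1, k_fusion=1.0, gamma=0.0)


@pytest.fixture
def small_sample():
    return CountSample(counts=np.array([1, 2, 3]), condition="toy")


def sample_stats(counts):
    """Plain mean/Fano of an integer array (test-side convenience)."""
    c = np.asarray(counts, dtype=float)
    return c.mean(), c.var(ddof=1) / c.mean()
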