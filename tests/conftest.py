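import numpy as np
import pytest

from sisoboost import BlobSpec, FeatureTable, make_benchmark_mimic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gauss_classes():
    """Two well-separated Gaussian classes: 20+20 points in R^10,
    class-mean separation 6, unit variance."""
    gen = np.random.default_rng(42)
    mean1 = np.zeros(10)
    mean0 = np.zeros(10)
    mean0[0] = 6.0
    X = np.vstack([
        gen.normal(size=(20, 10)) + mean1,
        gen.normal(size=(20, 10)) + mean0,
    ])
    y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
    return FeatureTable(ids=[f"s{i}" for i in range(40)], X=X, y=y)


@pytest.fixture
def line_table():
    """Four 1-D points at 0, 1, 2, 10."""
    X = np.array([[0.0], [1.0], [2.0], [10.0]])
    return FeatureTable(ids=list("abcd"), X=X)


@pytest.fixture(scope="session")
def mimic_pair():
    return make_benchmark_mimic(BlobSpec(seed=7, separation=4.0))
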