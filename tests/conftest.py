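import numpy as np
import pytest

from pipevolve import SynthSpec, generate_synthetic
from pipevolve.primitives import DEFAULT_REGISTRY

# Cost-bounded roster used by the evolutionary benchmarks: every transform
# plus the classifiers whose fits are milliseconds on desk-scale data.
FAST_CLASSIFIERS = ["gnb", "lda", "qda", "lr", "knn", "dt"]


@pytest.fixture(scope="session")
def fast_registry():
    return DEFAULT_REGISTRY.subset(
        DEFAULT_REGISTRY.transform_names() + FAST_CLASSIFIERS
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """Well-separated two-class data: 3 informative + 7 noise features."""
    return generate_synthetic(
        SynthSpec(n=200, p_informative=3, p_noise=7, separation=3.0, seed=7)
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Class-independent features: no classifier can beat the majority rate."""
    return generate_synthetic(
        SynthSpec(n=200, p_informative=3, p_noise=7, separation=0.0, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
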