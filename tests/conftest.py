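import numpy as np
import pytest

from tofoutlier.features import FeatureParams, build_feature_table
from tofoutlier.synth import GeneratorConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The full default synthetic cohort (533 measurements, 30 anomalies)."""
    return simulate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def default_features(default_dataset):
    return build_feature_table(default_dataset, FeatureParams())


@pytest.fixture(scope="session")
def small_config():
    """A fast, reduced cohort for I/O and pipeline smoke tests."""
    return GeneratorConfig(
        n_patients=10,
        n_measurements=80,
        n_outliers=8,
        n_outlier_patients=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
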