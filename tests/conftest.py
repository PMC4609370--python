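import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gasvr import FeatureTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(X, y, prefix="f"):
    """Build a FeatureTable from raw arrays with generated ids/names."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return FeatureTable(
        sample_ids=tuple(f"s{i:04d}" for i in range(X.shape[0])),
        feature_names=tuple(f"{prefix}{j}" for j in range(X.shape[1])),
        X=X,
        y=np.asarray(y, dtype=float),
    )


@pytest.fixture
def linear_table(rng):
    """60 samples x 6 features; y is a noiseless function of features 1 and 3."""
    X = rng.normal(size=(60, 6))
    y = 2.0 * X[:, 1] - 1.5 * X[:, 3]
    return make_table(X, y)
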