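import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hsvmcc.features import feature_table
from hsvmcc.synth import default_config, generate_training_set

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def train_windows():
    """Default 90-window balanced training set (15 windows x 6 activities)."""
    return generate_training_set(default_config(seed=0))


@pytest.fixture(scope="session")
def train_table(train_windows) -> pd.DataFrame:
    return feature_table(train_windows)


@pytest.fixture(scope="session")
def feature_cols(train_table):
    return [c for c in train_table.columns if c not in ("t_start", "label")]
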