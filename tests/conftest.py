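import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def small_counts_table():
    """3 features x 4 samples counts table with distinct column sums."""
    from tknet.tables import FeatureTable

    values = pd.DataFrame(
        {
            "s1": [2.0, 3.0, 5.0],
            "s2": [1.0, 1.0, 2.0],
            "s3": [0.0, 4.0, 6.0],
            "s4": [7.0, 2.0, 1.0],
        },
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
    )
    return FeatureTable(values=values, kind="counts")


@pytest.fixture
def two_group_meta():
    return pd.DataFrame(
        {
            "group": ["perturbed", "perturbed", "control", "control"],
            "experiment": ["exp_a"] * 4,
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
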