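import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def worked_example_matrix():
    """10 samples: 7 anchor-positive; companion in 6 of them + 2 anchor-negative.

    Reproduces the published worked example of the candidate-M-segment screen
    (V_co = 6/7, T_co = 6/8).
    """
    anchor = [1, 1, 1, 1, 1, 1, 1, 0, 0, 0]
    companion = [1, 1, 1, 1, 1, 1, 0, 1, 1, 0]
    return pd.DataFrame(
        {"tenui1_L": anchor, "candidate_M": companion},
        index=pd.Index([f"s{i}" for i in range(10)], name="sample"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
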