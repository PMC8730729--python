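import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_proteins():
    """Two-protein table used by the worked dSpC/dNSAF examples."""
    return pd.DataFrame({"protein_id": ["A", "B"], "length_aa": [100, 200]})
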