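import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dcmpanel.containers import CountsMatrix, ExpressionMatrix, SampleMetadata

settings.register_profile(
    "dcmpanel",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("dcmpanel")


@pytest.fixture
def small_counts() -> CountsMatrix:
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"S{i:02d}" for i in range(10)]
    values = rng.integers(0, 1000, size=(50, 10))
    return CountsMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    frame = pd.DataFrame(
        {
            "DCM_01": [1.0, 5.0, 2.0],
            "DCM_02": [2.0, 6.0, 2.1],
            "HS_01": [6.0, 1.0, 2.0],
            "HS_02": [8.0, 2.0, 1.9],
        },
        index=["GA", "GB", "GC"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    frame = pd.DataFrame(
        {
            "group": ["DCM", "DCM", "HS", "HS"],
            "batch": ["A", "A", "A", "A"],
        },
        index=["DCM_01", "DCM_02", "HS_01", "HS_02"],
    )
    return SampleMetadata(frame)
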