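import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from genecoord import ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def labeled_matrix() -> ExpressionMatrix:
    """5 genes x 5 samples with two groups, fixed values."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(size=(5, 5)),
        index=["LCK", "ZAP70", "CD44", "MAPT", "APP"],
        columns=[f"s{i}" for i in range(1, 6)],
    )
    groups = pd.Series(
        ["AD", "AD", "AD", "CON", "CON"], index=data.columns, name="group"
    )
    return ExpressionMatrix(data=data, groups=groups)
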