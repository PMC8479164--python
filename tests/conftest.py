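import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from pd1sig import ExpressionMatrix, filter_deg, make_construction_fixture


@pytest.fixture
def tiny_tpm():
    """5-gene x 3-sample TPM matrix with a tie."""
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [1.0, 2.0, 2.0, 3.0, 10.0],
                "s2": [5.0, 4.0, 3.0, 2.0, 1.0],
                "s3": [1.0, 1.0, 1.0, 1.0, 1.0],
            },
            index=["g1", "g2", "g3", "g4", "g5"],
        ),
        unit="TPM",
    )


@pytest.fixture(scope="session")
def construction_fixture():
    return make_construction_fixture(seed=0)


@pytest.fixture(scope="session")
def built_signature(construction_fixture):
    from pd1sig import build_signature

    fx = construction_fixture
    deg = filter_deg(fx.de_table)
    return build_signature(
        fx.cd8_specific, deg, fx.lines, fx.pd1hi_expr, fx.cells,
        cd8_expr=fx.cd8_expr, cd8_labels=fx.cd8_labels,
    )
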