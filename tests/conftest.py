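import numpy as np
import pandas as pd
import pytest

from migsfis import Cohort, FISModel, NormalizationSpec


@pytest.fixture
def small_df() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [70.0, 80.0, 65.0, 75.0, 90.0],
            "va": [0.2, 0.5, 0.1, 0.8, 0.3],
            "iop": [18.0, 25.0, 15.0, 30.0, 20.0],
            "vf": [-5.0, -12.0, -3.0, -20.0, -8.0],
            "drops": [2, 3, 1, 4, 2],
            "gtype": [6, 5, 1, 3, 2],
            "treatment": [4, 2, 1, 2, 1],
        }
    )


@pytest.fixture
def small_cohort(small_df) -> Cohort:
    return Cohort(small_df.copy())


@pytest.fixture
def two_rule_model() -> FISModel:
    """A hand-built 2-rule, 6-input Sugeno system on the normalized scale."""
    centers = np.array([[0.5, 0.2, 0.4, -0.3, 0.5, 0.8],
                        [-0.2, 0.6, -0.1, 0.4, 0.2, 0.3]])
    sigmas = np.full((2, 6), 0.4)
    consequents = np.array([[0.5, -0.2, 0.1, 0.0, 0.3, 0.2, 1.0],
                            [-0.1, 0.4, 0.0, 0.2, -0.3, 0.1, 3.0]])
    return FISModel(
        centers=centers,
        sigmas=sigmas,
        consequents=consequents,
        normalizer=NormalizationSpec(np.array([97.0, 1.4, 40.0, 33.0, 5.0, 6.0])),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
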