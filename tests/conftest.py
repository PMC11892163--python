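import numpy as np
import pandas as pd
import pytest

import survmediate as sm


@pytest.fixture(scope="session")
def female_params():
    return sm.default_params("female")


@pytest.fixture(scope="session")
def female_cohort(female_params):
    """Mid-sized complete cohort used by several modules' tests."""
    table, truth = sm.generate_cohort(female_params, 20_000, seed=101)
    return table, truth


@pytest.fixture(scope="session")
def design():
    return sm.SurveyDesign()


@pytest.fixture()
def toy_table():
    """Ten hand-checkable records with design columns and unit weights."""
    return pd.DataFrame({
        "y": [1, 1, 0, 0, 1, 0, 0, 0, 1, 0],
        "a": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
        "weight": np.ones(10),
        "stratum": [0] * 5 + [1] * 5,
        "psu": [0, 0, 1, 1, 2, 10, 10, 11, 11, 12],
    })
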