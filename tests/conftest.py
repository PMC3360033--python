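import math

import pytest

import microstab as ms


@pytest.fixture(scope="session")
def table2_profiles():
    return ms.load_table2()


@pytest.fixture(scope="session")
def table3_records():
    return ms.load_table3()


@pytest.fixture(scope="session")
def no_effect_params():
    """Study with the storage perturbation switched off entirely."""
    return ms.StudyParams(seed=11, condition_concentration=math.inf)


@pytest.fixture(scope="session")
def small_study(no_effect_params):
    return ms.generate_study(no_effect_params)
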