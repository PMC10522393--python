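import pytest

from npmodel import ModelParams, make_default_schedule

#: Calibrated human parameters: background probability deduced from
#: early-life incidence, threshold from the grid fit.
PC = 2.38e-18
Q = 118


@pytest.fixture(scope="session")
def uk_schedule():
    """The packaged 19-bracket UK schedule with its observed column."""
    return make_default_schedule()


@pytest.fixture(scope="session")
def human_params():
    return ModelParams(p_c=PC, q=Q)
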