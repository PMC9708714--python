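import dataclasses

import pytest

from hfref_cea.parameters import (
    AgeMortalityTable,
    base_case_parameters,
)


@pytest.fixture(scope="session")
def base():
    return base_case_parameters()


@pytest.fixture()
def flat_mortality_params(base):
    """Base case with background (non-CV) mortality switched off."""
    zero = AgeMortalityTable(bands=((0.0, 200.0, 0.0),))
    return dataclasses.replace(base, age_mortality=zero)
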