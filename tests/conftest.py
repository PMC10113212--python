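import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lineup_mpt import (
    ConditionSpec,
    ModelParameters,
    ResponseTable,
    base_restrictions,
    load_fixture,
)


@pytest.fixture
def exp2_tables():
    return load_fixture("exp2")


@pytest.fixture
def base_rs():
    return base_restrictions()


@pytest.fixture
def table2_like_params():
    """Parameter values in the region of the published estimates."""
    return ModelParameters(dP=0.27, b=0.15, g=0.59, dA=0.04, lineup_size=6)


def make_table(label, cp, ca, lineup_format="simultaneous", filler_type="morphed"):
    cond = ConditionSpec(label, lineup_format, filler_type, sum(cp), sum(ca))
    return ResponseTable(cond, *cp, *ca)


@pytest.fixture
def make_response_table():
    return make_table
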