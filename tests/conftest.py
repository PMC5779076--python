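import numpy as np
import pytest

from eadpredict import INITIAL_STATE, simulate
from eadpredict.drugs import load_drug_table


@pytest.fixture(scope="session")
def single_pace_trace():
    """One 3 s pace from the published initial conditions (baseline model)."""
    return simulate(INITIAL_STATE, duration=3000.0)


@pytest.fixture(scope="session")
def profiles():
    """Bundled drug table as a name -> DrugProfile mapping."""
    return {d.name: d for d in load_drug_table()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20211)
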