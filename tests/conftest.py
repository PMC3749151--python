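import numpy as np
import pandas as pd
import pytest

from taphomark.synthetic import (BlindTestSpec, PopulationSpec,
                                 simulate_blind_test, simulate_mark_population)

# Table 3 correspondence percentages (locating/diagnosing x abrasion
# included/excluded), used across the stats and scoring tests.
HAND_LOC_INC = [64, 61, 61, 56, 67, 69, 67, 58, 64, 58]
HAND_LOC_EXC = [63, 59, 60, 56, 70, 71, 71, 60, 63, 63]
HAND_DIA_INC = [30, 30, 28, 25, 33, 25, 31, 25, 25, 25]
HAND_DIA_EXC = [41, 41, 37, 33, 44, 33, 41, 33, 33, 33]
MICRO_LOC_INC = [58, 78, 75, 67, 67, 92]
MICRO_LOC_EXC = [63, 78, 78, 74, 74, 99]
MICRO_DIA_INC = [25, 42, 28, 44, 28, 56]
MICRO_DIA_EXC = [33, 48, 37, 48, 37, 67]
TT1 = [33, 30, 30, 25, 22, 22]
TT2 = [50, 39, 36, 36, 31, 28, 28, 28, 25, 25]


@pytest.fixture(scope="session")
def aquatic_marks() -> pd.DataFrame:
    table, _ = simulate_mark_population(
        PopulationSpec(group="aquatic", n_marks=40, seed=11),
        with_profiles=False)
    return table


@pytest.fixture(scope="session")
def blind_test_data(aquatic_marks):
    """Default-protocol simulated blind test: (responses, participants, key)."""
    return simulate_blind_test(BlindTestSpec(seed=21), aquatic_marks)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
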