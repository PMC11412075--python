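import numpy as np
import pandas as pd
import pytest

from phenoplast.simulate import ExperimentDesign, default_profiles, null_profiles, simulate
from phenoplast.traits import SCHEMA, TraitTable


def make_table(rows):
    """Build a TraitTable from (sid, family, block, trt, phase, trait, value) tuples."""
    return TraitTable.from_dataframe(pd.DataFrame(rows, columns=list(SCHEMA)))


@pytest.fixture(scope="session")
def small_design():
    return ExperimentDesign(n_families=6, replicates=3, blocks=2)


@pytest.fixture(scope="session")
def sim_table(small_design):
    return simulate(small_design, default_profiles(small_design, seed=7), seed=7)


@pytest.fixture(scope="session")
def full_design():
    return ExperimentDesign()  # 5 x 16 x 2 x 2


@pytest.fixture(scope="session")
def full_table(full_design):
    return simulate(full_design, seed=11)


@pytest.fixture(scope="session")
def null_table(small_design):
    return simulate(small_design, null_profiles(small_design), seed=0)
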