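import numpy as np
import pytest

from ptcl_cua import pipeline as pl
from ptcl_cua.synthetic_data import LifeTable, default_parameters, make_life_table


@pytest.fixture()
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def zero_life_table():
    ages = np.arange(0, 101)
    return LifeTable(ages, np.zeros_like(ages, dtype=float))


@pytest.fixture(scope="session")
def base_case():
    """Fully fitted base case (seed 1, jitter-free digitization) shared
    across integration tests; BaseCase.run never mutates it."""
    cfg = pl.RunConfig(seed=1, jitter_sd=0.0)
    return pl.build_base_case(cfg)
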