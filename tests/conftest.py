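import numpy as np
import pandas as pd
import pytest

from rumisotope import datasets, synthetic_data
from rumisotope.synthetic_data import SyntheticWorldConfig


@pytest.fixture(scope="session")
def small_world():
    """Three countries, 1961-1970, zero noise: exactly model-consistent."""
    return synthetic_data.generate_livestock_world(
        SyntheticWorldConfig(n_countries=3, year_start=1961, year_end=1970, seed=1)
    )


@pytest.fixture(scope="session")
def default_world():
    """The default ten-country 1961-2012 study world."""
    return synthetic_data.generate_livestock_world(SyntheticWorldConfig(seed=1))


@pytest.fixture(scope="session")
def co2_series():
    return synthetic_data.generate_co2_isotope_series()


@pytest.fixture(scope="session")
def observations():
    return datasets.load_diet_ch4_observations()


@pytest.fixture(scope="session")
def atmosphere():
    record, inventory = synthetic_data.generate_atmosphere_inputs()
    return record, inventory
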