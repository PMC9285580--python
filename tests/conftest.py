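import numpy as np
import pytest

from mpatimelines import SpeciesParams, get_species, load_species_table


@pytest.fixture(scope="session")
def table():
    return load_species_table()


@pytest.fixture(scope="session")
def by_name(table):
    def _get(name):
        return get_species(table, name)

    return _get


@pytest.fixture(scope="session")
def blue_rockfish(by_name):
    return by_name("Blue rockfish")


@pytest.fixture(scope="session")
def bocaccio(by_name):
    return by_name("Bocaccio")


@pytest.fixture(scope="session")
def urchin(by_name):
    return by_name("Red sea urchin")


def make_species(**overrides):
    """A plain, well-behaved synthetic species for focused unit tests."""
    base = dict(
        name="synthetic-test",
        max_age=40,
        L_mat=20.0,
        L_c=25.0,
        M=0.2,
        F=0.15,
        L_inf=50.0,
        k=0.2,
        a_0=-0.5,
        a_m=3,
        a_c=4,
        p=1e-5,
        w=3.0,
        sigma_R=0.5,
    )
    base.update(overrides)
    return SpeciesParams(**base)


@pytest.fixture
def synthetic():
    return make_species()
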