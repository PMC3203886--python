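import numpy as np
import pytest

from mtmix import fixtures as fx


@pytest.fixture(scope="session")
def db():
    """The bundled nine-row HVS-I database excerpt (8 distinct profiles)."""
    return fx.table1_database()


@pytest.fixture(scope="session")
def profs():
    """Excerpt profiles keyed by haplotype name (H20..H2575)."""
    return fx.table1_profiles()


@pytest.fixture(scope="session")
def table2():
    """(site labels, realized y1 column) of the quantitative table."""
    return fx.table2_sites(), fx.table2_y()


@pytest.fixture()
def rng():
    return np.random.default_rng(20111028)
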