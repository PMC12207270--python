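import numpy as np
import pytest

from regiocmd import bundled_pattern_table, parse_substrate
from regiocmd.pipeline import WORKED_EXAMPLE_SMILES


@pytest.fixture(scope="session")
def pattern_table():
    return bundled_pattern_table()


@pytest.fixture(scope="session")
def worked_example_smiles():
    return WORKED_EXAMPLE_SMILES


@pytest.fixture()
def phenylpyridine():
    return parse_substrate("c1ccc(-c2ccccn2)cc1")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
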