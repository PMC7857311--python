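import numpy as np
import pytest

from brainmech import GeneratorParams, generate_dataset, split_subsets
from brainmech.studies import default_study_table


@pytest.fixture(scope="session")
def study_table():
    return default_study_table()


@pytest.fixture(scope="session")
def records():
    """Default synthetic compilation (seed 0), generated once per session."""
    return generate_dataset(default_study_table(), GeneratorParams(seed=0))


@pytest.fixture(scope="session")
def subsets(records):
    return split_subsets(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
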