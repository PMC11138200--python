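import numpy as np
import pytest

from lesiongraph.synthetic import generate_dataset


@pytest.fixture(scope="session")
def synth_dataset():
    """400 synthetic lesions (200 per class) with their feature table.

    Shared across the suite; generation plus feature extraction runs once.
    """
    samples, table = generate_dataset(200, 200, seed=11)
    return samples, table


@pytest.fixture(scope="session")
def synth_table(synth_dataset):
    return synth_dataset[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
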