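import numpy as np
import pytest

from disfluency import (ThirdOctaveFrontend, ResidualDistanceExtractor,
                        generate_dataset)

BALANCED_COUNTS = {"block": 20, "repetition": 20, "prolongation": 20,
                   "fluent": 20}
SMALL_COUNTS = {"block": 4, "repetition": 4, "prolongation": 4, "fluent": 4}


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL_COUNTS, seed=0, difficulty="easy")


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    return ThirdOctaveFrontend().fit().transform(small_dataset)


@pytest.fixture(scope="session")
def balanced_features():
    """Residual-distance features of a balanced 80-utterance easy dataset,
    shared by the slower classifier tests."""
    ds = generate_dataset(BALANCED_COUNTS, seed=11, difficulty="easy")
    mats = ThirdOctaveFrontend().fit().transform(ds)
    F = ResidualDistanceExtractor(n_components=4).fit(mats).transform(mats)
    return F, ds.labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
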