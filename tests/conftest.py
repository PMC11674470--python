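import numpy as np
import pytest

from somnastage.preprocess import (concat_epoch_sets, epoch_and_align,
                                   preprocess_record)
from somnastage.synthetic import default_spec, generate_record


@pytest.fixture(scope="session")
def small_spec():
    """Small synthetic cohort spec shared across tests."""
    return default_spec(n_epochs=10, seed=7)


@pytest.fixture(scope="session")
def small_record(small_spec):
    return generate_record(small_spec, "rec-A")


@pytest.fixture(scope="session")
def small_epochset(small_spec):
    """Preprocessed epochs from a handful of records (3 channels)."""
    sets = []
    for i in range(8):
        rec = generate_record(small_spec, f"rec-{i}")
        eset, _ = epoch_and_align(preprocess_record(rec))
        sets.append(eset)
    return concat_epoch_sets(sets)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
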