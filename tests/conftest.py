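import numpy as np
import pytest

from morfmlp import FixtureConfig, default_scales, make_dataset, make_worked_example


@pytest.fixture(scope="session")
def scales():
    return default_scales()


@pytest.fixture(scope="session")
def worked():
    return make_worked_example()


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 short sequences with planted intervals and matching profiles."""
    return make_dataset(FixtureConfig(n_sequences=3, length_range=(60, 90),
                                      morf_length_range=(10, 20), seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_record(rng, length):
    from morfmlp.seq_io import ALPHABET, SequenceRecord

    letters = rng.choice(list(ALPHABET), size=length)
    return SequenceRecord(id="rnd", residues="".join(letters))
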