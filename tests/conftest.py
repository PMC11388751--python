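import numpy as np
import pytest

from ecgdetect.epochs import EpochMatrix, SyntheticConfig, generate_synthetic_ecg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_vt():
    return generate_synthetic_ecg(SyntheticConfig("VT", 40, seed=11))


@pytest.fixture
def small_nsr():
    return generate_synthetic_ecg(SyntheticConfig("NSR", 40, seed=12))


def make_matrix(data, labels=None, fs=1.0):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = ["VT"] * data.shape[0]
    return EpochMatrix(data, fs, np.asarray(labels, dtype=object))
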