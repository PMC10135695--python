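from pathlib import Path

import numpy as np
import pytest

from haarcodec import build_haar_matrix

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def kernel8():
    return build_haar_matrix(8)


@pytest.fixture(scope="session")
def kernel64():
    return build_haar_matrix(64)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ecg_fixture_path():
    return DATA_DIR / "synthetic_ecg_short.csv"


@pytest.fixture(scope="session")
def eeg_fixture_path():
    return DATA_DIR / "synthetic_eeg_short.csv"
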