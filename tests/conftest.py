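import numpy as np
import pytest

from binratio import BinauralSignal, MonoSignal, design_gammatone_bank


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bank():
    """Default analysis bank: 80 Hz – 10 kHz, two filters per ERB."""
    return design_gammatone_bank(80.0, 10_000.0, 2.0)


@pytest.fixture(scope="session")
def small_bank():
    """Light bank for fast tests (one filter per ERB up to 7 kHz)."""
    return design_gammatone_bank(100.0, 7_000.0, 1.0)


def white(duration, rate, seed=0):
    rng = np.random.default_rng(seed)
    return MonoSignal(rng.standard_normal(int(duration * rate)), rate)


def diotic(mono):
    return BinauralSignal(mono, mono)


@pytest.fixture
def white_10s_16k():
    return white(10.0, 16_000.0, seed=7)
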