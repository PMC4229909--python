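import numpy as np
import pytest

from copshmm import (
    GeneratorConfig, QuantizationParams, quantize, sample_profile,
    to_log_odds,
)


def make_profile(seed: int, M: int, alphabet: str = "DNA", **kw):
    return sample_profile(
        GeneratorConfig(seed=seed, M=M, alphabet=alphabet, **kw)
    )


def make_quantized(seed: int, M: int, alphabet: str = "DNA",
                   params: QuantizationParams | None = None):
    lo = to_log_odds(make_profile(seed, M, alphabet))
    return lo, quantize(lo, params or QuantizationParams())


def random_seq(rng, L: int, K: int = 4, p_degenerate: float = 0.0):
    """Random residue codes, optionally including the degenerate code K."""
    hi = K + 1 if p_degenerate > 0 else K
    s = rng.integers(0, hi, size=L)
    return s.astype(np.int16)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_profile():
    return make_profile(seed=7, M=3)


@pytest.fixture
def quantized_pair():
    """(LogOddsProfile, QuantizedProfile) for a mid-sized DNA model."""
    return make_quantized(seed=11, M=21)
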