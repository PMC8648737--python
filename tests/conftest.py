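import numpy as np
import pytest

from vocalsep import SynthPreset, make_corpus
from vocalsep.presets import SPECIES


@pytest.fixture(scope="session")
def toy():
    return SPECIES["toy"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_voice_preset():
    """Two individuals in disjoint F0 sub-bands (harmonics interleave without
    collisions), alias-safe at 8 kHz."""
    return SynthPreset(n_individuals=2, f0_band=(300.0, 800.0), n_harmonics=2,
                       duration_range=(0.15, 0.23))


@pytest.fixture(scope="session")
def two_voice_corpus(two_voice_preset):
    return make_corpus(two_voice_preset, calls_per_individual=12, seed=11)


@pytest.fixture(scope="session")
def six_voice_corpus():
    preset = SynthPreset(n_individuals=6, f0_band=(300.0, 1800.0), n_harmonics=2)
    return make_corpus(preset, calls_per_individual=12, seed=7)


def finite_difference_gradient(fn, x0, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    num = np.zeros_like(x0)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x0.copy()
        xp[i] += eps
        xm = x0.copy()
        xm[i] -= eps
        num[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return num
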