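import numpy as np
import pytest

from rhythmeg.synthetic import SyllableTrainSpec, gen_syllable_train


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def jittered_trains():
    """Thirty trains per rate condition with rate-dependent jitter."""
    trains = []
    for i, rate in enumerate((5.0, 11.0, 16.0)):
        for j in range(30):
            trains.append(gen_syllable_train(
                SyllableTrainSpec(rate=rate, jitter_sd=0.005 + 0.004 * i,
                                  n_syllables=20, seed=100 * i + j),
                sentence_id=f"s{i}_{j}"))
    return trains
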