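import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_sequence(rng, length, gc=0.30):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), p=probs, size=length))
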