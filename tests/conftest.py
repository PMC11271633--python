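import numpy as np
import pytest
from hypothesis import settings

from mammopt.datasets import PhantomConfig, generate_phantoms

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")

#: Study conditions for the desk-scale recovery experiments: one hundred
#: 64x64 phantoms, balanced classes, fixed seed, split 70/15/15.
STUDY_SEED = 7


@pytest.fixture(scope="session")
def phantoms64():
    return generate_phantoms(PhantomConfig(size=64, n_samples=100, seed=STUDY_SEED))


@pytest.fixture(scope="session")
def split70(phantoms64):
    rng = np.random.default_rng(STUDY_SEED)
    order = rng.permutation(len(phantoms64))
    return order[:70], order[70:85], order[85:]


@pytest.fixture(scope="session")
def phantoms32():
    return generate_phantoms(PhantomConfig(size=32, n_samples=40, seed=3))
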