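import numpy as np
import pytest

from ampdiv import CountVector, scrabble_population


@pytest.fixture(scope="session")
def scrabble():
    return scrabble_population()


@pytest.fixture
def small_vector():
    return CountVector(("v1", "v2", "v3"), np.array([3, 0, 2]))
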