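import numpy as np
import pytest

from hsq5d.sentiment import SentimentLexicons
from hsq5d.synthetic import scenario


@pytest.fixture(scope="session")
def tiny_lexicons() -> SentimentLexicons:
    """Hand-written fixture lexicon used across sentiment tests."""
    return SentimentLexicons(
        polarity={"good": 1.0, "kind": 1.0, "bad": -1.0, "rude": -1.0},
        degree={"very": 2.0, "slightly": 0.5},
        negation=frozenset({"not", "never"}),
    )


@pytest.fixture(scope="session")
def separable_bundle():
    """One noise-free, vocabulary-separable scenario shared by the suite."""
    return scenario("separable-small", seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
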