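import numpy as np
import pytest

from molcomplexity.ctm_bdm import build_ctm_table
from molcomplexity.synthetic import gen_string_corpus


@pytest.fixture(scope="session")
def ctm22():
    """Exhaustive (2,2) CTM table — small enough to build once per session."""
    return build_ctm_table(2, max_steps=107)


@pytest.fixture(scope="session")
def default_corpus():
    """The default 100+100 length-matched string corpus, seed 42."""
    return gen_string_corpus(seed=42)


def random_string(rng: np.random.Generator, length: int, alphabet_size: int) -> str:
    alpha = "abcdefgh"[:alphabet_size]
    return "".join(alpha[i] for i in rng.integers(alphabet_size, size=length))
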