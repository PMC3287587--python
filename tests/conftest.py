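import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqspectra import SymbolicSequence

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Worked-example repeat unit with a double cytosine (chromosome-6 style).
EXAMPLE_UNIT = "TAAGACCTATGTTAGTAAAG"


@pytest.fixture
def example_seq() -> SymbolicSequence:
    return SymbolicSequence(EXAMPLE_UNIT, "nucleotide", name="example")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_nucleotides(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
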