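import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from revtrace.reversion import LocusReference, PathogenicVariant
from revtrace.synthcohort import gen_locus, gen_pathogenic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def locus() -> LocusReference:
    """A 9 kb coding-frame locus (open reading frame in frame 0)."""
    return gen_locus(seed=11, length=9000, gc=0.5)


@pytest.fixture(scope="session")
def frameshift(locus) -> PathogenicVariant:
    """A 1-bp pathogenic frameshift deletion near the locus midpoint."""
    return gen_pathogenic(locus, "frameshift", seed=7)


@pytest.fixture(scope="session")
def stopgain(locus) -> PathogenicVariant:
    """A pathogenic stop-gain codon substitution."""
    return gen_pathogenic(locus, "stop_gain", seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20_24)
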