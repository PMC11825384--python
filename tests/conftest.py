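import itertools

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from shapemut import synth_table  # noqa: E402


def all_sequences(length):
    """Every DNA sequence of exactly the given length, lexicographic."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=length)]


def all_sequences_upto(max_length):
    out = []
    for L in range(1, max_length + 1):
        out.extend(all_sequences(L))
    return out


@pytest.fixture(scope="session")
def mgw_table():
    """Seeded synthetic pentamer table providing MGW only."""
    return synth_table(5, ["MGW"], 42)


@pytest.fixture(scope="session")
def full_table():
    """Seeded synthetic pentamer table providing all 14 features."""
    from shapemut import feature_catalogue

    return synth_table(5, [f.name for f in feature_catalogue()], 42)
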