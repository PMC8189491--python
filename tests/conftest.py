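"""Shared fixtures: one small synthetic city reused across module tests."""

import pytest

import tractprev as tp
from tractprev.keyword_selection import KeywordSet
from tractprev.vocab import DEFAULT_KEYWORDS


@pytest.fixture(scope="session")
def small_city() -> tp.SyntheticCity:
    """A light 60-tract city: quick to generate, enough structure to test on."""
    return tp.simulate_city(
        n_tracts=60, seed=11, users_per_capita=0.01, queries_per_user=5,
    )


@pytest.fixture(scope="session")
def default_keywords() -> KeywordSet:
    return KeywordSet(DEFAULT_KEYWORDS)


@pytest.fixture()
def grid_tracts() -> tp.TractSet:
    """A deterministic zero-jitter 3x3 grid on [0, 6]^2 km."""
    return tp.generate_tracts(9, region_size=6.0, jitter=0.0, seed=0, n_states=3)
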