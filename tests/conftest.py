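import pytest
from hypothesis import HealthCheck, settings

import addrlink as al

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


TRAIN_PROFILE = al.CorruptionProfile(
    typo=0.1, abbreviation=0.2, flat_flip=0.3, locality_dropout=0.1, county_insertion=0.1
)


@pytest.fixture(scope="session")
def gaz120():
    """Small toy gazetteer for unit-level pipeline tests."""
    return al.make_toy_gazetteer(120, seed=7)


@pytest.fixture(scope="session")
def linker120(gaz120):
    """A trained linker over the small gazetteer."""
    _, ann = al.make_benchmark(gaz120, 40, TRAIN_PROFILE, seed=21)
    return al.train_linker(gaz120, ann, seed=21, n_estimators=200)


@pytest.fixture(scope="session")
def gaz500():
    """The 500-record gazetteer used by the end-to-end recovery checks."""
    return al.make_toy_gazetteer(500, seed=11)


@pytest.fixture(scope="session")
def linker500(gaz500):
    """Linker trained on a low-corruption benchmark disjoint from evaluation."""
    _, ann = al.make_benchmark(gaz500, 140, TRAIN_PROFILE, seed=101)
    return al.train_linker(gaz500, ann, seed=101)
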