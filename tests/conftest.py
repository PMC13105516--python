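import pytest

from vlwelfare.model import ValueOfLostWelfare
from vlwelfare.synthetic import WorldSpec, generate_world, make_toy3


@pytest.fixture(scope="session")
def toy():
    """Three-country worked fixture with its hand-derived truth table."""
    return make_toy3()


@pytest.fixture(scope="session")
def toy_model(toy, tmp_path_factory):
    out = tmp_path_factory.mktemp("toy")
    return ValueOfLostWelfare.from_bundle(toy, tmp_dir=out)


@pytest.fixture(scope="session")
def world():
    """Default 204-country world, mild missingness and volatility."""
    return generate_world(WorldSpec(seed=42))


@pytest.fixture(scope="session")
def world_model(world, tmp_path_factory):
    out = tmp_path_factory.mktemp("world")
    return ValueOfLostWelfare.from_bundle(world, tmp_dir=out)


@pytest.fixture(scope="session")
def clean_world():
    """Zero-noise, zero-missingness world: pipeline should recover latents exactly."""
    return generate_world(WorldSpec(seed=7, missingness=0.0, volatility=0.0))


@pytest.fixture(scope="session")
def clean_model(clean_world, tmp_path_factory):
    out = tmp_path_factory.mktemp("clean")
    return ValueOfLostWelfare.from_bundle(clean_world, tmp_dir=out)
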