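import pytest

from benchmark_metadata import FixtureRecipe, generate_bundle, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_bundle(registry):
    """One project / 2 collections / 2 experiments each / 2 channels each."""
    return generate_bundle(
        registry,
        FixtureRecipe(seed=7, n_collections=2, n_experiments_per_collection=2,
                      n_channels_per_experiment=2),
    )


@pytest.fixture(scope="session")
def minimal_bundle(registry):
    return generate_bundle(registry, FixtureRecipe(seed=1))
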