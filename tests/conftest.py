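import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import morphoident as mi

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def taxonomy():
    return mi.load_taxonomy()


@pytest.fixture(scope="session")
def groups():
    return mi.load_character_groups()


@pytest.fixture(scope="session")
def small_genus():
    """A small, well-separated synthetic genus shared across tests."""
    spec = mi.GenusSpec(
        n_sections=3,
        species_per_section=3,
        collections_per_species=24,
        separation=3.0,
        missing_rate=0.1,
        seed=11,
    )
    tax, truth = mi.draw_genus(spec)
    records = mi.simulate_collections(truth, spec)
    return spec, tax, truth, records


@pytest.fixture(scope="session")
def fitted_small_identifier(small_genus, groups):
    """A calibrated species identifier on the small genus (CG7, single rate)."""
    spec, tax, _, records = small_genus
    config = mi.TrainingConfig(
        optimizer="adamw", amsgrad=True, learning_rates=(0.005,), seed=spec.seed
    )
    return mi.fit_identifier(
        records, groups["CG7"], mode="species", taxonomy=tax, config=config
    )


def make_record(values, collection_id="c1", species=None, continent=None):
    return mi.CollectionRecord(
        collection_id=collection_id, species=species, continent=continent,
        values=dict(values),
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
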