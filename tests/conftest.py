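import numpy as np
import pytest

from fawmarkers.marker_typing import HaplotypeRegistry, classify_collection
from fawmarkers.profiles import calls_table
from fawmarkers.synthetic_data import (
    PopulationSpec,
    build_panel,
    ecuador_fixture,
    simulate_collection,
)


@pytest.fixture(scope="session")
def fixture_collection():
    return ecuador_fixture()


@pytest.fixture(scope="session")
def fixture_calls(fixture_collection):
    registry = HaplotypeRegistry(fixture_collection.panel.registry_seed())
    calls, registry = classify_collection(fixture_collection.specimens, registry=registry)
    return calls, registry


@pytest.fixture(scope="session")
def fixture_table(fixture_collection, fixture_calls):
    calls, _ = fixture_calls
    return calls_table(fixture_collection.specimens, calls)


@pytest.fixture(scope="session")
def big_sim():
    """10,000 specimens, clean (no het-indels, no diagnostic-site edits)."""
    panel = build_panel(8, n_substitutions=3, n_indels=1, seed=11)
    spec = PopulationSpec(
        population_id="big",
        n=10_000,
        coi_freqs={"COI_RS": 0.05, "COI_h1": 0.1, "COI_h2": 0.6,
                   "COI_h3": 0.15, "COI_h4": 0.1},
        tpi_freqs={"TpiC": 0.8, "TpiR": 0.15, "TpiH": 0.05},
        intron_hap_freqs={h: 1 / 8 for h in panel.variants},
        het_indel_rate=0.0,
        male_fraction=0.5,
        seed=12345,
    )
    return simulate_collection([spec], panel), panel


@pytest.fixture
def rng():
    return np.random.default_rng(0)
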