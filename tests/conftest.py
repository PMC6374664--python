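import numpy as np
import pandas as pd
import pytest

from driftdiet.containers import DietMatrix, SampleTable
from driftdiet.synthetic import CommunityConfig, generate_reference_db, \
    simulate_diet_samples
from driftdiet.taxonomy import EsuTaxonomy


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured community: fast to simulate end to end."""
    return CommunityConfig(n_predator_species=3, n_esus=12,
                           n_samples_per_species_period=4,
                           rarefaction_depth=600, seed=11)


@pytest.fixture(scope="session")
def small_community(small_config):
    references, taxonomy = generate_reference_db(small_config)
    return small_config, references, taxonomy


@pytest.fixture(scope="session")
def simulated(small_community):
    config, references, taxonomy = small_community
    return simulate_diet_samples(config, taxonomy, references)


@pytest.fixture
def toy_taxonomy():
    """Two predators, three prey ESUs, one decoy."""
    table = pd.DataFrame({
        "esu": ["PredA_self", "PredB_self", "Mayfly", "Caddisfly", "Decoy"],
        "is_bilaterian": [True, True, True, True, False],
    })
    return EsuTaxonomy(esu_table=table,
                       self_esus={"PredA": {"PredA_self"},
                                  "PredB": {"PredB_self"}})


def make_diet(props: dict[str, list[float]], reads: list[int],
              species: list[str], period: list[str],
              dates: list[str] | None = None) -> DietMatrix:
    """Small DietMatrix builder for metric tests."""
    frame = pd.DataFrame(props)
    frame.index = [f"s{i}" for i in range(len(frame))]
    meta = pd.DataFrame({"predator_species": species, "period": period},
                        index=frame.index)
    if dates is not None:
        meta["date"] = dates
    return DietMatrix(frame, pd.Series(reads, index=frame.index), meta)


@pytest.fixture
def esu_sample_table(toy_taxonomy):
    counts = pd.DataFrame(
        {"PredA_self": [1900, 0, 1950, 1931],
         "PredB_self": [0, 1600, 0, 0],
         "Mayfly": [30, 150, 0, 14],
         "Caddisfly": [10, 50, 0, 5],
         "Decoy": [10, 50, 0, 0]},
        index=["a1", "b1", "a2", "a3"])
    meta = pd.DataFrame({
        "predator_species": ["PredA", "PredB", "PredA", "PredA"],
        "period": ["drift", "drift", "postdrift", "drift"],
    }, index=counts.index)
    return SampleTable(counts, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
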