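import datetime as dt

import numpy as np
import pytest

from collide.data_model import ChecklistRecord, CollisionRecord, SpeciesTraits
from collide.phylo import correlation_matrix
from collide.synthetic import ScenarioConfig, simulate_trees


@pytest.fixture
def traits_small():
    return [
        SpeciesTraits("woth", "yes", "forest", "lower", 1e7),
        SpeciesTraits("wavi", "no", "forest", "upper", 5e6),
        SpeciesTraits("swsp", "yes", "open", "lower", 2e6),
        SpeciesTraits("barn", "no", "open", "lower", 1e7, "diurnal_passerine"),
        SpeciesTraits("bcch", "no", "forest", "lower", 4e7, "resident"),
    ]


@pytest.fixture
def collision_records():
    d = dt.date
    return [
        CollisionRecord("woth", d(2015, 4, 10)),
        CollisionRecord("woth", d(2015, 4, 10)),
        CollisionRecord("woth", d(2015, 4, 12)),
        CollisionRecord("swsp", d(2015, 9, 20)),
        CollisionRecord("wavi", d(2015, 9, 21)),
        CollisionRecord("barn", d(2015, 4, 11)),
        CollisionRecord("bcch", d(2015, 1, 5)),
    ]


@pytest.fixture
def checklist_records():
    d = dt.date
    return [
        ChecklistRecord("woth", d(2015, 4, 10)),
        ChecklistRecord("woth", d(2015, 4, 11)),
        ChecklistRecord("wavi", d(2015, 4, 11)),
        ChecklistRecord("wavi", d(2015, 9, 20)),
        ChecklistRecord("swsp", d(2015, 9, 20)),
    ]


@pytest.fixture(scope="session")
def tree150():
    cfg = ScenarioConfig(n_species=150, n_trees=1, seed=42)
    return simulate_trees(cfg)[0]


@pytest.fixture(scope="session")
def corr150(tree150):
    return correlation_matrix(tree150, sorted(tree150.tip_labels))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
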