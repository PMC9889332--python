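import warnings

import numpy as np
import pandas as pd
import pytest

from divfacets.io import CommunityMatrix, Phylogeny, TraitTable
from divfacets.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # metric-level warnings (degenerate hulls, NaN betas) are expected noise
    # in many tests; tests that assert on warnings re-enable them locally
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def toy_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_community() -> CommunityMatrix:
    return CommunityMatrix(
        site_ids=["s1", "s2", "s3"],
        species_ids=["A", "B", "C"],
        incidence=np.array([[1, 1, 0], [1, 0, 1], [0, 1, 0]]),
        habitat=["forest", "savannah", "farmland"],
        elevation_m=np.array([2000.0, 1400.0, 1500.0]),
    )


@pytest.fixture
def toy_traits() -> TraitTable:
    df = pd.DataFrame(
        {
            "svl": [20.0, 60.0, 40.0],
            "tadpole_type": ["lentic", "lentic", "lotic"],
            "webbing": [0.0, 2.0, 1.0],
        },
        index=["A", "B", "C"],
    )
    return TraitTable(
        data=df,
        kinds={"svl": "continuous", "tadpole_type": "categorical", "webbing": "ordinal"},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Small but fully structured synthetic dataset, shared across tests."""
    cfg = SimulationConfig(
        n_species_forest=10, n_species_savannah=8, n_species_farmland=8,
        n_sites={"forest": 5, "savannah": 5, "farmland": 6},
        n_species_grid_extra=10, n_cells=20, hotspot_cells=[9, 10],
        range_size_distribution={"kind": "uniform", "low": 3, "high": 15},
        seed=42,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(cfg)
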