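import numpy as np
import pandas as pd
import pytest

from saprocom.data_model import CommunityTable, SurveyDesign
from saprocom.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated survey shared by read-only tests."""
    cfg = SimulationConfig(n_species=40, n_years=8, paper_design=False,
                           n_logs_per_tree=6)
    return simulate_dataset(cfg, seed=11)


@pytest.fixture
def toy_design():
    logs = pd.DataFrame({
        "log_id": ["L1", "L2", "L3", "L4"],
        "tree_species": ["spruce", "fir", "beech", "spruce"],
        "plot_id": ["p1", "p2", "p3", "p4"],
        "E": [0.0, 100.0, 200.0, 300.0],
        "N": [0.0, 50.0, 100.0, 150.0],
        "exposure_start": [2013, 2012, 2012, 2013],
    })
    return SurveyDesign(logs=logs, sampling_years=(2013, 2014, 2015, 2016),
                        missing_years=frozenset())


@pytest.fixture
def toy_community():
    rec = pd.DataFrame({
        "log_id": ["L1", "L1", "L1", "L2", "L2", "L3", "L4"],
        "exposure_year": [0, 0, 1, 1, 2, 1, 0],
        "species_id": ["a", "b", "a", "a", "c", "d", "e"],
        "count": [3, 1, 2, 5, 1, 4, 2],
    })
    return CommunityTable(rec)
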