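import numpy as np
import pandas as pd
import pytest

from andescarbon import SimulationConfig, generate_species_pool, simulate_network
from andescarbon.census import pair_censuses


@pytest.fixture(scope="session")
def small_network():
    """Six-plot synthetic network at default demographic settings."""
    return simulate_network(SimulationConfig(n_plots=6, seed=11))


@pytest.fixture(scope="session")
def small_pairs(small_network):
    return pair_censuses(small_network.census, small_network.plots)


@pytest.fixture(scope="session")
def species_pool():
    return generate_species_pool(SimulationConfig(n_plots=2, n_species_pool=40, seed=3))


@pytest.fixture
def toy_tree_newick():
    # ((A:1,B:1):1,C:2); total branch length 5
    return "((A:1,B:1):1,C:2);"


@pytest.fixture
def micro_pair():
    """Hand-built census pair: 2 survivors, 1 death, 1 recruit on 0.5 ha."""
    from andescarbon.census import PlotCensusPair

    survivors = pd.DataFrame(
        {
            "tag": ["s1", "s2"],
            "species": ["spA", "spB"],
            "genus": ["gA", "gB"],
            "family": ["fA", "fB"],
            "dbh1": [20.0, 30.0],
            "dbh2": [22.0, 30.5],
            "wd": [0.6, 0.7],
        }
    )
    deaths = pd.DataFrame(
        {
            "tag": ["d1"],
            "species": ["spA"],
            "genus": ["gA"],
            "family": ["fA"],
            "dbh1": [25.0],
            "wd": [0.6],
        }
    )
    recruits = pd.DataFrame(
        {
            "tag": ["r1"],
            "species": ["spB"],
            "genus": ["gB"],
            "family": ["fB"],
            "dbh2": [11.0],
            "wd": [0.7],
        }
    )
    return PlotCensusPair(
        plot_id="p1",
        area_ha=0.5,
        elevation_m=1500.0,
        latitude=-5.0,
        longitude=-75.0,
        t_years=4.0,
        date_first=pd.Timestamp("2005-06-01"),
        date_last=pd.Timestamp("2009-06-01"),
        survivors=survivors,
        deaths=deaths,
        recruits=recruits,
    )


@pytest.fixture
def mm2_valuer():
    """TreeValuer on an exactly known Michaelis-Menten height curve."""
    from andescarbon.allometry import HeightDiameterModel, TreeValuer

    rng = np.random.default_rng(0)
    dbh = rng.uniform(5.0, 80.0, 60)
    height = 40.0 * dbh / (20.0 + dbh)
    model = HeightDiameterModel().fit(dbh, height)
    return TreeValuer(model)
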