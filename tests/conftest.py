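"""Shared fixtures: designs, tiny hand-built datasets, seeded simulations."""

from pathlib import Path

import pandas as pd
import pytest

from beniforest.model import (
    SiteDesign,
    SurveyDataset,
    default_designs,
    validate_dataset,
)
from beniforest.synthetic import default_profiles, simulate_survey

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def designs():
    return default_designs()


@pytest.fixture(scope="session")
def grazed_design(designs):
    return designs[0]


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def sim_dataset():
    """One seeded default two-site campaign, shared across tests."""
    return simulate_survey(seed=20250925)


@pytest.fixture
def two_plot_dataset():
    """Two plots, one with 2 adult broadleafs, the other empty."""
    design = SiteDesign(site_id="grazed", treatment="grazed", n_plots=2)
    stems = pd.DataFrame(
        [
            {"site_id": "grazed", "plot_id": "grazed-P1", "stage": "adult",
             "group": "broadleaf", "dbh_cm": 20.0, "height_m": None,
             "alive": True, "grazing_damage": False},
            {"site_id": "grazed", "plot_id": "grazed-P1", "stage": "adult",
             "group": "broadleaf", "dbh_cm": 30.0, "height_m": None,
             "alive": True, "grazing_damage": False},
        ]
    )
    return validate_dataset(SurveyDataset(designs={"grazed": design}, stems=stems))


def make_sapling(site, plot, group, height, dbh=None, alive=True):
    return {
        "site_id": site, "plot_id": plot, "stage": "sapling", "group": group,
        "dbh_cm": dbh, "height_m": height, "alive": alive, "grazing_damage": False,
    }


@pytest.fixture
def nr_toy_dataset():
    """Two-plot toy: plot1 has 2 motacú + 1 broadleaf in class 1–2 m,
    plot2 one broadleaf in class 2–3 m."""
    design = SiteDesign(site_id="grazed", treatment="grazed", n_plots=2)
    stems = pd.DataFrame(
        [
            make_sapling("grazed", "grazed-P1", "motacu", 1.5),
            make_sapling("grazed", "grazed-P1", "motacu", 1.8),
            make_sapling("grazed", "grazed-P1", "broadleaf", 1.2, dbh=2.0),
            make_sapling("grazed", "grazed-P2", "broadleaf", 2.5, dbh=3.0),
        ]
    )
    return validate_dataset(SurveyDataset(designs={"grazed": design}, stems=stems))
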