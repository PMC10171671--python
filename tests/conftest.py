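import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sodium_cra as sc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return sc.load_parameters()


@pytest.fixture(scope="session")
def intake_table():
    return sc.load_intake_table()


@pytest.fixture(scope="session")
def adult_baseline(intake_table):
    adult = intake_table[intake_table["sex"] != "total"]
    return adult.rename(
        columns={"baseline_mean_mg": "mean_mg", "baseline_sd_mg": "sd_mg"}
    )[["sex", "age_group", "n", "mean_mg", "sd_mg"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def adult_scenario_a(intake_table):
    adult = intake_table[intake_table["sex"] != "total"]
    return adult.rename(
        columns={"scenarioA_mean_mg": "mean_mg", "scenarioA_sd_mg": "sd_mg"}
    )[["sex", "age_group", "mean_mg", "sd_mg"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def population_baseline_mean(intake_table):
    row = intake_table[intake_table["sex"] == "total"]
    return float(row["baseline_mean_mg"].iloc[0])


@pytest.fixture(scope="session")
def mortality():
    return sc.generate_demography(sc.SyntheticConfig())


@pytest.fixture
def toy_products():
    return pd.DataFrame({
        "product_id": ["p1", "p2", "p3", "p4", "p5"],
        "category_id": ["soup", "soup", "bread", "bread", None],
        "sodium_mg_per_100g": [900.0, 400.0, 700.0, 550.0, 1000.0],
    })


@pytest.fixture
def toy_targets():
    return pd.DataFrame({
        "category_id": ["soup", "bread"],
        "target_mg_per_100g": [600.0, 600.0],
    })
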