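import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from pollenkit import (
    ExpressionTable,
    PanelParams,
    SpecificityCriteria,
    build_test_plasmid,
    simulate_expression_panel,
)


@pytest.fixture(scope="session")
def plasmid():
    return build_test_plasmid(seed=11)


@pytest.fixture(scope="session")
def noise_free_panel():
    params = PanelParams(
        n_genes=500, n_specific=50, leak_fraction=0.1, noise_sd=0.0, seed=5
    )
    tables, truth = simulate_expression_panel(params)
    return params, tables, truth


@pytest.fixture()
def recovery_criteria(noise_free_panel):
    params, _, _ = noise_free_panel
    return SpecificityCriteria(tau_on=5.0, tau_off=params.background_level)


def make_table(values, classes, platform):
    """Small hand-written expression table helper."""
    df = pd.DataFrame(values).T.astype(float)
    return ExpressionTable(df, classes, platform)


@pytest.fixture()
def tiny_mpss():
    classes = {"pollen_lib": "pollen", "leaf": "vegetative", "root": "vegetative"}
    values = {
        "gA": {"pollen_lib": 1200.0, "leaf": 0.0, "root": 0.0},
        "gB": {"pollen_lib": 0.0, "leaf": 0.0, "root": 0.0},
        "gC": {"pollen_lib": 900.0, "leaf": 3.0, "root": 0.0},
        "gD": {"pollen_lib": 1001.0, "leaf": 0.0, "root": 0.0},
        "gE": {"pollen_lib": 1000.0, "leaf": 0.0, "root": 0.0},
    }
    return make_table(values, classes, "mpss")
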