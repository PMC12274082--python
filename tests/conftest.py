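"""Shared fixtures: small synthetic panels and resolved generator configs."""

import logging

import numpy as np
import pandas as pd
import pytest

from longmec.panel import Panel
from longmec import simulate as sim

logging.getLogger("longmec").setLevel(logging.ERROR)

#: 15%-prevalence outcome coefficients (weak interaction scenario)
BETA_WEAK = (-3.0, np.log(1.2), 0.5, -np.log(1.1), np.log(1.2))
#: 5%-prevalence outcome coefficients (strong interaction scenario)
BETA_STRONG = (-3.0, np.log(1.2), 0.5, -np.log(1.5), np.log(1.1))


def make_panel(rows, covariates=("W",)):
    """Build a Panel from (id, time, y, C, c, W, role) tuples."""
    df = pd.DataFrame(rows, columns=["id", "time", "y", "C", "c", "W", "role"])
    return Panel(df, covariates=covariates)


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(n1=300, n2=150, beta=BETA_WEAK, seed=7)


@pytest.fixture(scope="session")
def small_resolved(small_config):
    return sim.resolve_config(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_resolved):
    """One MS/EVS draw at modest size, shared across read-only tests."""
    return sim.generate_dataset(small_config, 20240901, small_resolved)


@pytest.fixture(scope="session")
def ivs_config():
    return sim.SimulationConfig(n1=300, n2=150, beta=BETA_WEAK,
                                design="ms_ivs", seed=7)


@pytest.fixture(scope="session")
def ivs_dataset(ivs_config):
    resolved = sim.resolve_config(ivs_config)
    return sim.generate_dataset(ivs_config, 20240902, resolved)
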