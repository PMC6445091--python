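"""Shared fixtures: study configuration, calibrated parameters, grids.

Calibration and the full scenario grid are expensive (tens of seconds),
so they are session-scoped and shared across the acceptance and property
tests.
"""

from __future__ import annotations

import time

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nfixclim as nx

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return nx.default_config()


@pytest.fixture(scope="session")
def tropical_params(config):
    return nx.load_parameterization("tropical", config)


@pytest.fixture(scope="session")
def calibration(config):
    """(calibrated config, per-biome CalibrationResult, wall time in s)."""
    start = time.monotonic()
    calcfg, results = nx.calibrated_config(config)
    return calcfg, results, time.monotonic() - start


@pytest.fixture(scope="session")
def calibrated_config_fx(calibration):
    return calibration[0]


@pytest.fixture(scope="session")
def experiment_grid(calibrated_config_fx):
    """Full calibrated scenario grid (all biomes) with its wall time."""
    start = time.monotonic()
    grid = nx.run_experiment_grid(calibrated_config_fx)
    return grid, time.monotonic() - start


@pytest.fixture(scope="session")
def tropical_obligate_trajectory(calibrated_config_fx):
    scenario = nx.Scenario("tropical", "obligate", "intermediate_2006", "intermediate")
    return nx.run_scenario(calibrated_config_fx, scenario)
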