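"""Shared fixtures: solved steady states are expensive, so session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from fatrans.config import ModelConfig, default_config
from fatrans.steady_state import solve_steady_state, tune_metabolic_rate
from fatrans.synthetic_data import experiment_config


@pytest.fixture(scope="session")
def config_a() -> ModelConfig:
    """Experiment A: intermediate albumin (0.11 mmol/l), flow 0.035 s^-1."""
    return experiment_config("A")


@pytest.fixture(scope="session")
def steady_a(config_a):
    """Steady state of experiment A with R_met tuned to extraction 0.12."""
    R = tune_metabolic_rate(config_a)
    return solve_steady_state(config_a, R)


@pytest.fixture(scope="session")
def coarse_config() -> ModelConfig:
    """Cheap configuration (few z cells, fixed R_met) for solver unit tests."""
    cfg = default_config(R_met=300.0)
    data = cfg.model_dump()
    data["numerics"]["n_z"] = 24
    data["numerics"]["dt"] = 0.05
    data["numerics"]["t_max"] = 150.0
    return ModelConfig.model_validate(data)


@pytest.fixture(scope="session")
def coarse_steady(coarse_config):
    return solve_steady_state(coarse_config, coarse_config.experiment.R_met)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
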