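"""Shared fixtures: small calibrated cohorts reused across test modules."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import rtisim as rs

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def scaled_config(scenario: str, sample_rate: float, seed: int = 1,
                  **overrides) -> rs.RunConfig:
    cfg = rs.default_config(scenario)
    cfg = dataclasses.replace(
        cfg, seed=seed,
        population=dataclasses.replace(cfg.population, sample_rate=sample_rate,
                                       seed=seed))
    for path, value in overrides.items():
        cfg = rs.replace_in_config(cfg, path.replace("__", "."), value)
    return cfg


@pytest.fixture(scope="session")
def small_yhec():
    """Calibrated 1/10,000-scale YHEC setup (32,926 persons)."""
    return rs.prepare(scaled_config("yhec", 1e-4))


@pytest.fixture(scope="session")
def small_cochrane():
    return rs.prepare(scaled_config("cochrane", 1e-4))


@pytest.fixture(scope="session")
def small_yhec_ledger(small_yhec):
    return small_yhec.run(11)


@pytest.fixture(scope="session")
def small_cochrane_ledger(small_cochrane):
    return small_cochrane.run(11)


@pytest.fixture(scope="session")
def tiny_pop():
    """~3,300-person cohort for structural checks."""
    cfg = scaled_config("yhec", 1e-5)
    return rs.generate_population(cfg.population)
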