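import dataclasses

import pytest

from serocircuit import BatteryConfig, ModelParams, SimulationSettings
from serocircuit.battery import run_battery

pytest_plugins = []

try:  # derandomise hypothesis when present
    from hypothesis import settings as hyp_settings

    hyp_settings.register_profile("ci", derandomize=True, max_examples=50)
    hyp_settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def default_settings() -> SimulationSettings:
    return SimulationSettings()


@pytest.fixture
def fast_settings() -> SimulationSettings:
    """Short protocol for contract/shape tests (not for quantitative checks)."""
    return SimulationSettings(dt=1e-4, duration=0.5, transient=0.1, n_reps=3,
                              base_seed=2024)


@pytest.fixture(scope="session")
def battery_table():
    """Full 48-condition grid at the published protocol (n=100, default seed).

    Session-scoped: the quantitative acceptance checks all read from this
    one run.
    """
    return run_battery(BatteryConfig())


def get_value(table, condition, treatment, variant, region, observable,
              column="mean"):
    rows = table[(table.condition == condition) & (table.treatment == treatment)
                 & (table.variant == variant) & (table.region == region)
                 & (table.observable == observable)]
    assert len(rows) == 1, (condition, treatment, variant, region, observable)
    return float(rows.iloc[0][column])


@pytest.fixture
def value_getter():
    return get_value


def tiny_settings(**overrides) -> SimulationSettings:
    base = dict(dt=1e-4, duration=0.3, transient=0.1, n_reps=2, base_seed=7)
    base.update(overrides)
    return SimulationSettings(**base)


@pytest.fixture
def make_tiny_settings():
    return tiny_settings


def replace(obj, **kw):
    return dataclasses.replace(obj, **kw)
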