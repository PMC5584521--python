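import warnings

import pytest

from alkflux import (
    HEXADECANE,
    NoiseModel,
    SimulationConfig,
    generate_experiment,
    load_reference_endpoints,
    methanogenic_yields,
)


@pytest.fixture(scope="session")
def hexadecane_yields():
    return methanogenic_yields(HEXADECANE)


@pytest.fixture(scope="session")
def reference_endpoints():
    return load_reference_endpoints()


@pytest.fixture(scope="session")
def noise_free_config():
    """Study-condition defaults with measurement noise switched off."""
    return SimulationConfig(noise_sd=NoiseModel.none())


@pytest.fixture(scope="session")
def noise_free_observations(noise_free_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # low-sulfate treatments cap the partition law
        return generate_experiment(noise_free_config)


@pytest.fixture(scope="session")
def replete_config():
    """Sulfate-replete variant (1 l liquid): the partition law is uncapped
    at every sulfate level, so S/M = beta * C0 holds exactly."""
    return SimulationConfig(noise_sd=NoiseModel.none(), liquid_volume_l=1.0)


@pytest.fixture(scope="session")
def replete_observations(replete_config):
    return generate_experiment(replete_config)


def net_series(obs, config):
    """Net methane and net sulfate reduced per observation row."""
    out = obs.copy()
    out["M"] = out["methane_mmol"] - config.background_methane
    out["S"] = (
        out["initial_sulfate_mM"] * config.liquid_volume_l
        - out["sulfate_mmol"]
        - config.background_sulfate
    )
    return out
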