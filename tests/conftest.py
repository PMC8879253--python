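"""Shared fixtures.

The calibrated kinetic model (joint glucose+glycerol fit of the packaged
datasets) is expensive (~minutes), so it is built once per session and shared
by the fitting and acceptance tests.
"""

import warnings

import pytest

from dhaflux import fitting, kinetics, netcore, stoich

warnings.filterwarnings("ignore", message="lsoda")


@pytest.fixture(scope="session")
def kinetic_network():
    return netcore.build_kinetic_network()


@pytest.fixture(scope="session")
def kinetic_model():
    return kinetics.build_kinetic_model()


@pytest.fixture(scope="session")
def stoich_model():
    return stoich.build_stoich_model()


@pytest.fixture(scope="session")
def calibrated_model(kinetic_model):
    """Kinetic model fitted jointly to the packaged glucose+glycerol datasets."""
    datasets = [fitting.load_packaged_dataset("glucose"),
                fitting.load_packaged_dataset("glycerol")]
    config = fitting.packaged_calibration_config(
        "glucose_glycerol", kinetic_model, seed=1)
    result = fitting.fit_parameters(kinetic_model, datasets, config)
    return fitting.apply_parameters(kinetic_model, result.parameters)


@pytest.fixture(scope="session")
def steady_states(calibrated_model):
    """Steady states of the calibrated model for the three scenarios."""
    out = {}
    for substrate, uptake in [("glucose", 3.58), ("glycerol", 2.42),
                              ("ethanol", 7.76)]:
        scen = kinetics.configure_scenario(calibrated_model, substrate, uptake)
        out[substrate] = kinetics.find_steady_state(scen)
    return out
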