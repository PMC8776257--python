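"""Shared fixtures: populations, calibrated scaling, reference parameter sets."""

import numpy as np
import pytest

from btspsim import (InductionProtocol, RuleParams, make_calibration_targets,
                     make_input_population, make_synthetic_cell,
                     make_trajectory)
from btspsim.network import network_rule_params
from btspsim.params import single_spike_reference_params
from btspsim.ramp import calibrate_scaling
from btspsim.simulate import InductionSimulator, background_for


@pytest.fixture(scope="session")
def pop():
    return make_input_population()


@pytest.fixture(scope="session")
def scaling(pop):
    """Calibrated voltage scale and reference weight-profile width."""
    return calibrate_scaling(pop)


@pytest.fixture(scope="session")
def background(pop, scaling):
    return background_for(pop, scaling[0])


@pytest.fixture(scope="session")
def spike_params():
    return single_spike_reference_params()


@pytest.fixture(scope="session")
def invivo_params():
    """Mean parameter estimates from in vivo place-cell inductions."""
    return RuleParams(tau_ET=863.91, tau_IS=542.76, alpha_pot=0.24,
                      beta_pot=30.32, alpha_dep=0.09, beta_dep=2260.61,
                      k_pot=2.27, k_dep=0.33, W_max=4.02)


@pytest.fixture(scope="session")
def network_params():
    """Frozen rule parameters calibrated for the network model."""
    return network_rule_params()


@pytest.fixture(scope="session")
def calibration_targets():
    return make_calibration_targets()


@pytest.fixture(scope="session")
def calibration_sims(pop, scaling, calibration_targets):
    de_novo, transloc = calibration_targets
    c, _ = scaling
    return (InductionSimulator(pop, de_novo.trajectory, de_novo.protocol, c),
            InductionSimulator(pop, transloc.trajectory, transloc.protocol,
                               c))


@pytest.fixture(scope="session")
def silent_cell(network_params, pop, scaling):
    """De novo induction in an initially silent cell (noise-free)."""
    c, sw = scaling
    return make_synthetic_cell(
        network_params, pop, None,
        InductionProtocol(plateau_position=120.0),
        make_trajectory(n_laps=3), c=c, sigma_w=sw)


@pytest.fixture(scope="session")
def translocation_cell(network_params, pop, scaling):
    """Cell with a pre-existing field roughly opposite the plateau site."""
    c, sw = scaling
    return make_synthetic_cell(
        network_params, pop, (45.0, 8.0),
        InductionProtocol(plateau_position=120.0),
        make_trajectory(n_laps=3), c=c, sigma_w=sw)
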