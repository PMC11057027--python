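import numpy as np
import pytest

import meltkin as mk


@pytest.fixture(scope="session")
def thermal_params():
    """Lumped thermal model calibrated to the 280 K plateau / ~11 us rise anchors."""
    return mk.calibrate_thermal()


@pytest.fixture(scope="session")
def kinetics_params():
    """Default bulk crystallization kinetics, anchored to R_c = 1e8 K/s."""
    return mk.default_kinetics()


@pytest.fixture(scope="session")
def basis():
    return mk.default_basis()


@pytest.fixture(scope="session")
def rect_trajectory(thermal_params):
    pulse = mk.build_pulse(1.0, 30e-6)
    return mk.simulate_temperature(pulse, thermal_params)


@pytest.fixture()
def constant_c_params():
    """Constant heat capacity, zero latent heat: the linear-ODE limit."""
    k = 5e5
    return mk.ThermalParams(
        loss_coefficient=k,
        heat_capacity_table=((50.0, 1.5), (400.0, 1.5)),
        latent_heat_fusion=0.0,
        absorbed_hold_power=k * 180.0,
    )


def zero_nucleation_kinetics(geometry="bulk"):
    """Kinetics with J effectively zero everywhere."""
    T = np.array([100.0, 200.0, 280.0])
    return mk.KineticsParams(
        nucleation_table=tuple(zip(T, [-300.0] * 3)),
        growth_table=tuple(zip(T, [-3.0] * 3)),
        geometry=geometry,
    )
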