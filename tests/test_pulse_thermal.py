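"""Pulse construction and lumped thermal simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meltkin as mk
from meltkin.errors import (
    CalibrationError,
    InvalidParameterError,
    NeverMeltsError,
)


class TestBuildPulse:
    def test_rectangular_pulse_is_single_segment(self):
        p = mk.build_pulse(1.0, 30e-6, 1.0, 0.0)
        assert p.segments == ((0.0, 30e-6, 1.0),)
        assert p.total_duration == 30e-6

    @pytest.mark.parametrize(
        "mult,dur",
        [(17.5, 450e-9), (9.0, 1e-6)],
    )
    def test_spiked_pulse_has_two_segments(self, mult, dur):
        p = mk.build_pulse(1.0, 30e-6, mult, dur)
        assert p.segments == ((0.0, dur, mult), (dur, 30e-6, 1.0))

    @pytest.mark.parametrize(
        "args",
        [
            (1.0, 30e-6, 0.5, 1e-6),   # multiplier < 1
            (1.0, 1e-6, 2.0, 2e-6),    # spike longer than pulse
            (1.0, 30e-6, 2.0, -1e-9),  # negative duration
        ],
    )
    def test_invalid_parameters_rejected(self, args):
        with pytest.raises(InvalidParameterError):
            mk.build_pulse(*args)

    @pytest.mark.parametrize(
        "mult,dur,expected",
        [
            (1.0, 0.0, 0.0),
            (9.0, 1e-6, 8.0e-6),
            (17.5, 450e-9, 7.425e-6),
        ],
    )
    def test_spike_excess_fluence(self, mult, dur, expected):
        p = mk.build_pulse(1.0, 30e-6, mult, dur)
        assert mk.spike_excess_fluence(p) == pytest.approx(expected, rel=1e-12)


@given(
    mult=st.floats(1.0, 50.0),
    dur=st.floats(1e-9, 20e-6),
    total=st.floats(21e-6, 40e-6),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_pulse_invariants_for_any_admissible_spike(mult, dur, total):
    p = mk.build_pulse(1.0, total, mult, dur)
    starts = [s[0] for s in p.segments]
    ends = [s[1] for s in p.segments]
    assert starts[0] == 0.0 and ends[-1] == p.total_duration == total
    assert all(e > s for s, e in zip(starts, ends))
    assert starts[1:] == ends[:-1]
    assert all(s[2] >= 0 for s in p.segments)
    assert mk.spike_excess_fluence(p) == pytest.approx(
        (mult - 1.0) * dur, rel=1e-9, abs=1e-30
    )


class TestSimulateTemperature:
    def test_zero_power_stays_at_bath(self, thermal_params):
        pulse = mk.build_pulse(0.0, 30e-6)
        traj = mk.simulate_temperature(pulse, thermal_params)
        assert np.allclose(traj.temperatures, 100.0, atol=1e-6)
        assert np.all(traj.melt_fraction == 0.0)

    def test_constant_c_matches_closed_form(self, constant_c_params):
        """Linear first-order ODE: T(t) = plateau + (bath - plateau) e^{-t/tau}."""
        pulse = mk.build_pulse(1.0, 30e-6)
        traj = mk.simulate_temperature(pulse, constant_c_params)
        tau = constant_c_params.areal_mass * 1.5 / constant_c_params.loss_coefficient
        T_cf = 280.0 + (100.0 - 280.0) * np.exp(-traj.times / tau)
        below = T_cf < 273.0  # enthalpy map pins at the melting point above
        err = np.abs(traj.temperatures[below] - T_cf[below]) / T_cf[below]
        assert err.max() < 1e-6

    def test_hold_power_approaches_plateau(self, constant_c_params):
        pulse = mk.build_pulse(1.0, 60e-6)
        traj = mk.simulate_temperature(pulse, constant_c_params)
        assert traj.temperatures[-1] == pytest.approx(280.0, abs=0.1)

    def test_rectangular_pulse_reaches_melting_within_11us(self, rect_trajectory):
        t_cross = rect_trajectory.first_crossing(273.0)
        assert t_cross < 11.5e-6
        assert rect_trajectory.temperatures[-1] >= 273.0

    def test_melt_fraction_only_after_melting_point(self, thermal_params):
        pulse = mk.build_pulse(1.0, 30e-6, 17.5, 450e-9)
        traj = mk.simulate_temperature(pulse, thermal_params)
        molten = traj.melt_fraction > 0
        assert np.all(traj.temperatures[molten] >= mk.T_MELT - 1e-6)
        assert np.all(np.diff(traj.melt_fraction) >= -1e-12)

    def test_energy_conservation_negligible_loss(self):
        """With negligible loss, absorbed energy equals stored enthalpy."""
        k = 1e-6  # W/K, effectively lossless
        params = mk.ThermalParams(
            loss_coefficient=k,
            heat_capacity_table=((50.0, 1.5), (400.0, 1.5)),
            latent_heat_fusion=334.0,
            absorbed_hold_power=k * 180.0,
        )
        power_multiple = 2.5e10  # W in hold-power units against the tiny k
        pulse = mk.build_pulse(power_multiple, 30e-6)
        traj = mk.simulate_temperature(pulse, params)
        absorbed = power_multiple * params.absorbed_hold_power * traj.times[-1]
        T_end = traj.temperatures[-1]
        stored = 1.5 * (min(T_end, mk.T_MELT) - 100.0) + 334.0 * traj.melt_fraction[-1]
        if T_end > mk.T_MELT:
            stored += 4.2 * (T_end - mk.T_MELT)
        assert stored == pytest.approx(absorbed, rel=1e-3)

    def test_comparison_principle(self, thermal_params):
        """Pointwise stronger pulses give pointwise hotter trajectories."""
        rng = np.random.default_rng(11)
        for _ in range(8):
            m_lo = rng.uniform(1.0, 8.0)
            m_hi = m_lo + rng.uniform(0.5, 8.0)
            d = rng.uniform(0.2e-6, 3e-6)
            lo = mk.simulate_temperature(
                mk.build_pulse(1.0, 30e-6, m_lo, d), thermal_params, t_max=10e-6
            )
            hi = mk.simulate_temperature(
                mk.build_pulse(1.0, 30e-6, m_hi, d), thermal_params, t_max=10e-6
            )
            assert np.all(hi.temperatures >= lo.temperatures - 1e-6)


class TestCalibration:
    def test_anchors_reproduced(self, thermal_params, rect_trajectory):
        # steady-state plateau within 1 K by construction
        balance = thermal_params.loss_coefficient * (280.0 - 100.0)
        assert thermal_params.absorbed_hold_power == pytest.approx(balance, rel=1e-9)
        # melting-point crossing within 2% of the requested rise time
        assert rect_trajectory.first_crossing(mk.T_MELT) == pytest.approx(
            11e-6, rel=0.02
        )

    def test_rectangular_average_rate_near_1_6e7(self, rect_trajectory):
        res = mk.average_heating_rate(rect_trajectory)
        assert res.rate == pytest.approx(1.6e7, rel=0.10)

    def test_constant_c_limit_recovers_analytic_time_constant(self):
        """tau = rise_time / ln(180 / 6.85) for a constant heat capacity."""
        rise = 10.8e-6
        params = mk.calibrate_thermal(
            280.0, rise, 100.0, heat_capacity_table=((50.0, 1.5), (400.0, 1.5))
        )
        tau = params.areal_mass * 1.5 / params.loss_coefficient
        tau_expected = rise / np.log(180.0 / (280.0 - mk.T_MELT))
        assert tau == pytest.approx(tau_expected, rel=1e-3)

    def test_plateau_below_melting_fails(self):
        with pytest.raises(CalibrationError):
            mk.calibrate_thermal(plateau=260.0, rise_time_to_273K=11e-6, bath=100.0)


class TestHeatingRateAndMelting:
    def test_linear_ramp_rate_exact(self):
        R = 2.5e7
        t = np.linspace(0, 8e-6, 500)
        traj = mk.ThermalTrajectory(
            times=t, temperatures=100.0 + R * t, melt_fraction=np.zeros_like(t)
        )
        assert mk.average_heating_rate(traj).rate == pytest.approx(R, rel=1e-9)

    def test_piecewise_trajectory_matches_dense_resampling_oracle(self):
        """Mid-ramp pause: compare against a brute-force crossing search."""
        t = np.array([0.0, 1e-6, 2e-6, 3e-6, 4e-6, 5e-6])
        T = np.array([90.0, 150.0, 150.0, 210.0, 273.5, 279.0])
        traj = mk.ThermalTrajectory(times=t, temperatures=T,
                                    melt_fraction=np.zeros_like(t))
        res = mk.average_heating_rate(traj)
        # oracle: dense linear resampling, first indices above each level
        td = np.linspace(t[0], t[-1], 2_000_001)
        Td = np.interp(td, t, T)
        t_lo = td[np.argmax(Td >= 100.0)]
        t_hi = td[np.argmax(Td >= 273.0)]
        assert res.rate == pytest.approx(173.0 / (t_hi - t_lo), rel=1e-4)

    def test_rate_strictly_increasing_in_spike_multiplier(self, thermal_params):
        rates = []
        for mult in np.linspace(1.0, 20.0, 8):
            pulse = mk.build_pulse(1.0, 30e-6, mult, 450e-9)
            traj = mk.simulate_temperature(pulse, thermal_params, t_max=12e-6)
            rates.append(mk.average_heating_rate(traj).rate)
        assert np.all(np.diff(rates) > 0)

    def test_never_reaching_273_raises(self, thermal_params):
        pulse = mk.build_pulse(0.0, 30e-6)
        traj = mk.simulate_temperature(pulse, thermal_params)
        with pytest.raises(NeverMeltsError):
            mk.average_heating_rate(traj)

    def test_melting_time_zero_latent_equals_crossing(self):
        k = 5e5
        params = mk.ThermalParams(
            loss_coefficient=k,
            heat_capacity_table=((50.0, 1.5), (400.0, 1.5)),
            latent_heat_fusion=0.0,
            absorbed_hold_power=k * 180.0,
        )
        traj = mk.simulate_temperature(mk.build_pulse(1.0, 30e-6), params)
        assert mk.melting_time(traj) == pytest.approx(
            traj.first_crossing(mk.T_MELT), rel=1e-6
        )

    def test_spiked_pulse_melts_below_600ns(self, thermal_params):
        pulse = mk.build_pulse(1.0, 30e-6, 17.5, 450e-9)
        traj = mk.simulate_temperature(pulse, thermal_params, t_max=5e-6)
        assert mk.melting_time(traj) <= 600e-9

    def test_melting_slower_than_latent_free_bound(self, thermal_params):
        """Latent heat delays completion: 173 K / rate <= melting time."""
        pulse = mk.build_pulse(1.0, 30e-6, 17.5, 450e-9)
        traj = mk.simulate_temperature(pulse, thermal_params, t_max=5e-6)
        res = mk.average_heating_rate(traj)
        assert 173.0 / res.rate <= mk.melting_time(traj)

    def test_rectangular_pulse_melt_stalls_within_pulse(self, rect_trajectory):
        """The hold power barely exceeds the loss at the melting point, so a
        rectangular pulse cannot finish melting within its 30 us duration."""
        with pytest.raises(NeverMeltsError):
            mk.melting_time(rect_trajectory)


class TestDesignMinimalSpike:
    def test_threshold_one_needs_no_spike(self, thermal_params, kinetics_params):
        assert mk.design_minimal_spike(thermal_params, kinetics_params, 1e-6, 1.0) == 1.0

    def test_rectangular_pulse_crystallizes_so_spike_needed(
        self, thermal_params, kinetics_params
    ):
        mult = mk.design_minimal_spike(thermal_params, kinetics_params, 1e-6, 0.01)
        assert mult > 1.0

    def test_longer_spike_needs_no_higher_multiplier(
        self, thermal_params, kinetics_params
    ):
        m1 = mk.design_minimal_spike(thermal_params, kinetics_params, 1e-6, 0.01)
        m2 = mk.design_minimal_spike(thermal_params, kinetics_params, 2e-6, 0.01)
        assert m2 <= m1 * 1.02
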