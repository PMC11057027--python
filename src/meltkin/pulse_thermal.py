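"""Shaped laser pulses and lumped-capacitance thermal simulation.

A thin amorphous-ice film sitting on a laser-heated support is modelled as a
single thermal mass exchanging heat with a cold bath:

    m c(T) dT/dt = P_abs(t) - k (T - T_bath)

where ``P_abs(t)`` is the absorbed laser power (a piecewise-constant multiple
of the hold power), ``k`` a linear loss coefficient and ``c(T)`` the specific
heat of the sample.  Melting at 273.15 K is handled with the enthalpy method:
the state variable integrated is the specific enthalpy ``H``, and the
temperature is pinned at the melting point while latent heat is consumed, with
the melt fraction tracked explicitly.

The model is calibrated to two experimental anchors — the steady-state plateau
temperature reached under a plain rectangular pulse and the time the sample
takes to heat from the bath temperature to the melting point — which together
fix the loss coefficient and the absorbed hold power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .errors import (
    CalibrationError,
    IntegrationError,
    InvalidParameterError,
    NeverMeltsError,
    SearchFailureError,
)

T_MELT = 273.15
"""Melting point of ice, K."""


# ---------------------------------------------------------------------------
# Pulse shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseShape:
    """Piecewise-constant laser power versus time.

    Powers are expressed as multiples of the hold power (the level that keeps
    the molten sample at its plateau temperature), so a plain rectangular
    pulse is a single segment at power 1.

    Parameters
    ----------
    segments
        Ordered ``(t_start, t_end, power)`` triples in seconds and hold-power
        units.  Segments must tile ``[0, total_duration]`` contiguously.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if not self.segments:
            raise InvalidParameterError("pulse needs at least one segment")
        prev_end = 0.0
        for t0, t1, p in self.segments:
            if not (math.isfinite(t0) and math.isfinite(t1) and math.isfinite(p)):
                raise InvalidParameterError("non-finite pulse segment")
            if t1 <= t0:
                raise InvalidParameterError(f"segment [{t0}, {t1}] has t_start >= t_end")
            if abs(t0 - prev_end) > 1e-15:
                raise InvalidParameterError("pulse segments must be contiguous")
            if p < 0:
                raise InvalidParameterError("pulse power must be >= 0")
            prev_end = t1

    @property
    def total_duration(self) -> float:
        return self.segments[-1][1]

    def power(self, t: np.ndarray | float) -> np.ndarray:
        """Absorbed power (hold-power units) at time ``t``; 0 outside the pulse."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for t0, t1, p in self.segments:
            out = np.where((t >= t0) & (t < t1), p, out)
        return out


def build_pulse(
    hold_power_multiple: float,
    total_duration: float,
    spike_multiplier: float = 1.0,
    spike_duration: float = 0.0,
) -> PulseShape:
    """Build a hold pulse with an optional leading intensity spike.

    The spike occupies ``[0, spike_duration]`` at ``spike_multiplier`` times
    the hold power; the remainder of the pulse runs at ``hold_power_multiple``
    (normally 1).  ``spike_duration = 0`` yields a plain rectangular pulse.
    """
    if spike_duration < 0 or total_duration <= spike_duration:
        raise InvalidParameterError(
            "need total_duration > spike_duration >= 0, got "
            f"{total_duration} and {spike_duration}"
        )
    if spike_multiplier < 1:
        raise InvalidParameterError("spike_multiplier must be >= 1")
    if hold_power_multiple < 0:
        raise InvalidParameterError("hold power must be >= 0")
    if spike_duration == 0 or spike_multiplier == hold_power_multiple:
        return PulseShape(((0.0, total_duration, hold_power_multiple),))
    return PulseShape(
        (
            (0.0, spike_duration, spike_multiplier * hold_power_multiple),
            (spike_duration, total_duration, hold_power_multiple),
        )
    )


def spike_excess_fluence(pulse: PulseShape) -> float:
    """Energy delivered above the hold level, in hold-power x seconds.

    This is the integral of ``P(t) - 1`` over the segments that exceed the
    hold level; pulse shapes designed for a common heating budget keep this
    quantity constant while trading spike intensity against duration.
    """
    excess = 0.0
    for t0, t1, p in pulse.segments:
        if p > 1.0:
            excess += (p - 1.0) * (t1 - t0)
    return excess


# ---------------------------------------------------------------------------
# Thermal parameters
# ---------------------------------------------------------------------------

def _default_heat_capacity_table() -> tuple[tuple[float, float], ...]:
    # Textbook-style specific heat of ice, piecewise linear in T.
    return ((100.0, 0.8), (T_MELT, 2.1))


@dataclass(frozen=True)
class ThermalParams:
    """Parameters of the lumped energy balance.

    Attributes
    ----------
    bath_temperature, plateau_temperature : K
        Cold-bath temperature and the steady-state temperature the sample
        reaches under the hold power.
    loss_coefficient : W/K
        Linear heat-loss coefficient of the lumped sample.
    heat_capacity_table : ((T, c), ...)
        Specific heat of the solid, J/(g K), interpolated linearly in T.
    liquid_heat_capacity : J/(g K)
    latent_heat_fusion : J/g
    areal_mass : g
        Effective lumped sample mass.
    absorbed_hold_power : W
        Absorbed power at hold level; at steady state it balances the loss,
        ``absorbed_hold_power = loss_coefficient * (plateau - bath)``.
    """

    bath_temperature: float = 100.0
    plateau_temperature: float = 280.0
    loss_coefficient: float = 1.0
    heat_capacity_table: tuple[tuple[float, float], ...] = field(
        default_factory=_default_heat_capacity_table
    )
    liquid_heat_capacity: float = 4.2
    latent_heat_fusion: float = 334.0
    areal_mass: float = 1.0
    absorbed_hold_power: float = 180.0

    def __post_init__(self):
        vals = [
            self.bath_temperature,
            self.plateau_temperature,
            self.loss_coefficient,
            self.liquid_heat_capacity,
            self.latent_heat_fusion,
            self.areal_mass,
            self.absorbed_hold_power,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("non-finite thermal parameter")
        if self.bath_temperature >= self.plateau_temperature:
            raise InvalidParameterError("bath temperature must lie below the plateau")
        if any(c <= 0 for _, c in self.heat_capacity_table):
            raise InvalidParameterError("heat capacity must be positive")
        if self.latent_heat_fusion < 0:
            raise InvalidParameterError("latent heat must be >= 0")
        if self.areal_mass <= 0 or self.loss_coefficient <= 0:
            raise InvalidParameterError("mass and loss coefficient must be positive")
        balance = self.loss_coefficient * (self.plateau_temperature - self.bath_temperature)
        if not math.isclose(self.absorbed_hold_power, balance, rel_tol=1e-6):
            raise InvalidParameterError(
                "absorbed_hold_power must equal loss_coefficient * (plateau - bath); "
                f"got {self.absorbed_hold_power} vs {balance}"
            )

    def solid_heat_capacity(self, T: np.ndarray | float) -> np.ndarray:
        tab = np.asarray(self.heat_capacity_table, dtype=float)
        return np.interp(np.asarray(T, dtype=float), tab[:, 0], tab[:, 1])


class _EnthalpyMap:
    """Monotone map between temperature and specific enthalpy (J/g).

    Reference H = 0 at the bath temperature.  Solid branch integrates c(T);
    a flat segment of width ``latent_heat_fusion`` sits at the melting point;
    the liquid branch is linear with the liquid heat capacity.
    """

    def __init__(self, params: ThermalParams, n_grid: int = 2048):
        self.params = params
        T0 = min(params.bath_temperature, params.heat_capacity_table[0][0])
        Tg = np.linspace(T0, T_MELT, n_grid)
        c = params.solid_heat_capacity(Tg)
        Hg = cumulative_trapezoid(c, Tg, initial=0.0)
        # shift reference so H(bath) = 0
        Hg -= np.interp(params.bath_temperature, Tg, Hg)
        self._Tg = Tg
        self._Hg = Hg
        self.H_melt_start = float(Hg[-1])
        self.H_melt_end = self.H_melt_start + params.latent_heat_fusion

    def temperature(self, H: np.ndarray | float) -> np.ndarray:
        H = np.asarray(H, dtype=float)
        solid = np.interp(H, self._Hg, self._Tg)
        liquid = T_MELT + (H - self.H_melt_end) / self.params.liquid_heat_capacity
        out = np.where(H <= self.H_melt_start, solid, T_MELT)
        return np.where(H >= self.H_melt_end, liquid, out)

    def melt_fraction(self, H: np.ndarray | float) -> np.ndarray:
        H = np.asarray(H, dtype=float)
        L = self.params.latent_heat_fusion
        if L == 0:
            return (H >= self.H_melt_start).astype(float)
        return np.clip((H - self.H_melt_start) / L, 0.0, 1.0)

    def enthalpy(self, T: float) -> float:
        if T > T_MELT:
            return self.H_melt_end + (T - T_MELT) * self.params.liquid_heat_capacity
        return float(np.interp(T, self._Tg, self._Hg))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalTrajectory:
    """Simulated sample temperature and melt fraction versus time."""

    times: np.ndarray
    temperatures: np.ndarray
    melt_fraction: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("trajectory times must be strictly increasing")
        if len(self.temperatures) != len(t) or len(self.melt_fraction) != len(t):
            raise InvalidParameterError("trajectory arrays must share one length")

    def first_crossing(self, T_level: float) -> float:
        """First time the temperature reaches ``T_level`` (linear interpolation)."""
        T = self.temperatures
        if T[0] >= T_level:
            return float(self.times[0])
        above = np.nonzero(T >= T_level)[0]
        if len(above) == 0:
            raise NeverMeltsError(f"trajectory never reaches {T_level} K")
        i = above[0]
        t0, t1 = self.times[i - 1], self.times[i]
        f = (T_level - T[i - 1]) / (T[i] - T[i - 1])
        return float(t0 + f * (t1 - t0))


@dataclass(frozen=True)
class HeatingRateResult:
    """Average heating rate between two temperature crossings."""

    rate: float
    t_at_100K: float
    t_at_273K: float


def _time_grid(pulse: PulseShape, t_max: float | None, min_points_per_segment: int,
               max_dt: float) -> np.ndarray:
    """Union of per-segment grids resolving every segment with >= the minimum."""
    end = pulse.total_duration if t_max is None else t_max
    pieces = []
    for t0, t1, _ in pulse.segments:
        if t0 >= end:
            break
        t1 = min(t1, end)
        n = max(min_points_per_segment, int(np.ceil((t1 - t0) / max_dt)) + 1)
        pieces.append(np.linspace(t0, t1, n))
    if end > pulse.total_duration:
        n = max(min_points_per_segment, int(np.ceil((end - pulse.total_duration) / max_dt)) + 1)
        pieces.append(np.linspace(pulse.total_duration, end, n))
    grid = np.unique(np.concatenate(pieces))
    return grid


def simulate_temperature(
    pulse: PulseShape,
    params: ThermalParams,
    t_max: float | None = None,
    min_points_per_segment: int = 50,
    max_dt: float = 20e-9,
    rtol: float = 1e-8,
) -> ThermalTrajectory:
    """Integrate the lumped energy balance along a shaped pulse.

    The specific enthalpy is the integrated state, which makes the melting
    plateau (enthalpy method) a smooth part of one scalar ODE.  The output
    grid resolves every pulse segment with at least ``min_points_per_segment``
    samples and never exceeds ``max_dt`` between samples.
    """
    emap = _EnthalpyMap(params)
    k = params.loss_coefficient
    m = params.areal_mass
    P0 = params.absorbed_hold_power
    Tb = params.bath_temperature
    grid = _time_grid(pulse, t_max, min_points_per_segment, max_dt)

    H_parts = [np.array([0.0])]
    H_cur = 0.0
    atol = 1e-10 * max(1.0, emap.H_melt_end)
    boundaries = [t0 for t0, _, _ in pulse.segments] + [pulse.total_duration]
    end = grid[-1]
    seg_edges = [b for b in boundaries if b < end] + [end]
    for i, (ta, tb_) in enumerate(zip(seg_edges[:-1], seg_edges[1:])):
        p = float(pulse.power(0.5 * (ta + tb_)))

        def rhs(t, y, p=p):
            T = emap.temperature(y[0])
            return [(P0 * p - k * (T - Tb)) / m]

        t_eval = grid[(grid > ta) & (grid <= tb_)]
        sol = solve_ivp(
            rhs, (ta, tb_), [H_cur], t_eval=t_eval, method="LSODA",
            rtol=rtol, atol=atol, max_step=(tb_ - ta),
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed on segment {i} [{ta:g}, {tb_:g}] s: {sol.message}"
            )
        H_parts.append(sol.y[0])
        H_cur = float(sol.y[0][-1]) if len(sol.y[0]) else H_cur
    H = np.concatenate(H_parts)[: len(grid)]
    T = emap.temperature(H)
    phi = emap.melt_fraction(H)
    return ThermalTrajectory(times=grid, temperatures=T, melt_fraction=phi)


# ---------------------------------------------------------------------------
# Calibration and metrics
# ---------------------------------------------------------------------------

def calibrate_thermal(
    plateau: float = 280.0,
    rise_time_to_273K: float = 11e-6,
    bath: float = 100.0,
    heat_capacity_table: tuple[tuple[float, float], ...] | None = None,
    liquid_heat_capacity: float = 4.2,
    latent_heat_fusion: float = 334.0,
    areal_mass: float = 1.0,
) -> ThermalParams:
    """Fix the loss coefficient and hold power from two experimental anchors.

    Under a rectangular pulse the solid-phase balance reads
    ``m c(T) dT/dt = k (plateau - T)``, so the time to heat from the bath to
    the melting point is ``(m/k) * I`` with ``I = int c(T)/(plateau - T) dT``.
    Inverting this gives the loss coefficient in closed form; the hold power
    follows from the steady-state condition.
    """
    if not (bath < T_MELT < plateau):
        raise CalibrationError(
            f"need bath < {T_MELT} K < plateau; got bath={bath}, plateau={plateau}",
            residuals={"plateau_margin": plateau - T_MELT},
        )
    if rise_time_to_273K <= 0:
        raise CalibrationError("rise time must be positive")
    table = heat_capacity_table or _default_heat_capacity_table()
    probe = ThermalParams(
        bath_temperature=bath,
        plateau_temperature=plateau,
        heat_capacity_table=table,
        liquid_heat_capacity=liquid_heat_capacity,
        latent_heat_fusion=latent_heat_fusion,
        areal_mass=areal_mass,
        loss_coefficient=1.0,
        absorbed_hold_power=plateau - bath,
    )
    Tg = np.linspace(bath, T_MELT, 4096)
    integ = np.trapezoid(probe.solid_heat_capacity(Tg) / (plateau - Tg), Tg)
    k = areal_mass * integ / rise_time_to_273K
    params = replace(
        probe,
        loss_coefficient=k,
        absorbed_hold_power=k * (plateau - bath),
    )
    # verify the anchors on the actual integrator
    horizon = max(6.0 * rise_time_to_273K, rise_time_to_273K + 1e-6)
    traj = simulate_temperature(
        build_pulse(1.0, horizon), params, max_dt=horizon / 4000,
    )
    t_cross = traj.first_crossing(T_MELT)
    if abs(t_cross - rise_time_to_273K) > 0.02 * rise_time_to_273K:
        raise CalibrationError(
            "calibrated model misses the rise-time anchor",
            residuals={"t_cross": t_cross, "target": rise_time_to_273K},
        )
    return params


def average_heating_rate(
    traj: ThermalTrajectory, T_lo: float = 100.0, T_hi: float = 273.0
) -> HeatingRateResult:
    """Mean heating rate between the first crossings of ``T_lo`` and ``T_hi``.

    Defined as the temperature span divided by the elapsed time between the
    two crossings, i.e. the time-average of dT/dt over that stretch.
    """
    t_lo = traj.first_crossing(T_lo)
    try:
        t_hi = traj.first_crossing(T_hi)
    except NeverMeltsError:
        raise NeverMeltsError(
            f"trajectory never reaches {T_hi} K; cannot define a heating rate"
        ) from None
    if t_hi <= t_lo:
        raise InvalidParameterError("upper crossing does not follow the lower one")
    return HeatingRateResult(
        rate=(T_hi - T_lo) / (t_hi - t_lo), t_at_100K=t_lo, t_at_273K=t_hi
    )


def melting_time(traj: ThermalTrajectory) -> float:
    """Time from pulse onset until the melt fraction first reaches 1."""
    phi = traj.melt_fraction
    done = np.nonzero(phi >= 1.0)[0]
    if len(done) == 0:
        raise NeverMeltsError("melt fraction never reaches 1")
    i = done[0]
    if i == 0:
        return float(traj.times[0])
    if phi[i - 1] == 0.0:
        # zero-latent-heat limit: the melt fraction is a step, so the
        # completion time is the melting-point crossing itself
        return traj.first_crossing(T_MELT)
    f = (1.0 - phi[i - 1]) / (phi[i] - phi[i - 1])
    return float(traj.times[i - 1] + f * (traj.times[i] - traj.times[i - 1]))


def design_minimal_spike(
    params: ThermalParams,
    kinetics,
    spike_duration: float,
    crystalline_threshold: float,
    total_duration: float = 30e-6,
    probe_window: float = 10e-6,
    multiplier_bound: float = 64.0,
    rel_tol: float = 0.01,
) -> float:
    """Smallest spike multiplier keeping the crystalline fraction below a threshold.

    Runs a bisection (to ``rel_tol`` relative precision) on the spike
    multiplier of a fixed-duration leading spike, evaluating the final
    crystalline fraction of the simulated trajectory with the given
    crystallization kinetics.
    """
    from .kinetics import crystallized_fraction

    if not (0 < crystalline_threshold <= 1):
        raise InvalidParameterError("threshold must be in (0, 1]")
    if spike_duration <= 0:
        raise InvalidParameterError("spike_duration must be positive")
    if crystalline_threshold >= 1.0:
        return 1.0  # X = 1 - exp(-ext) < 1 always: any pulse suffices

    def final_fraction(mult: float) -> float:
        pulse = build_pulse(1.0, total_duration, mult, spike_duration)
        traj = simulate_temperature(pulse, params, t_max=probe_window)
        res = crystallized_fraction(traj, kinetics)
        return float(res.fraction[-1])

    if final_fraction(1.0) < crystalline_threshold:
        return 1.0
    if final_fraction(multiplier_bound) >= crystalline_threshold:
        raise SearchFailureError(
            f"threshold {crystalline_threshold} unreachable below multiplier "
            f"{multiplier_bound}"
        )
    lo, hi = 1.0, multiplier_bound
    while (hi - lo) > rel_tol * lo:
        mid = 0.5 * (lo + hi)
        if final_fraction(mid) < crystalline_threshold:
            hi = mid
        else:
            lo = mid
    return hi
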