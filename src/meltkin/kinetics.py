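"""Nucleation-and-growth crystallization kinetics along thermal trajectories.

Crystallization of supercooled water during flash heating is governed by the
opposite temperature trends of the nucleation rate J(T) — fast at deep
supercooling, vanishing near the melting point — and the crystal growth speed
u(T), which surges at high temperature.  A heated amorphous sample therefore
first collects nuclei at low temperature and then grows them rapidly; only a
sufficiently high heating rate traverses the dangerous window fast enough to
leave no detectable crystalline fraction.

The transformed fraction follows the Kolmogorov / Johnson-Mehl-Avrami law for
continuous nucleation with isotropic growth:

    X(t) = 1 - exp( -K_d  int_0^t J(T(tau)) [ int_tau^t u(T(s)) ds ]^(n-1) dtau )

with K_3D = 4 pi / 3 (bulk, Avrami exponent n = 4) and K_2D = pi (surface
nucleation in a thin film, n = 3).  Crystallization is suppressed once the
sample is fully molten above the melting point: stable liquid does not
freeze.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .errors import InvalidParameterError, SearchFailureError
from .pulse_thermal import T_MELT, ThermalTrajectory

_GEOMETRY_CONSTANTS = {"bulk": (4.0 * np.pi / 3.0, 4), "surface": (np.pi, 3)}


@dataclass(frozen=True)
class KineticsParams:
    """Temperature-dependent crystallization kinetics.

    Attributes
    ----------
    nucleation_table : (T, log10 J) pairs
        Nucleation rate table, events per unit volume (bulk) or area
        (surface) per second; interpolated log-linearly in T.
    growth_table : (T, log10 u) pairs
        Crystal growth speed table, length per second.
    avrami_exponent : int
        n = growth dimension + 1 for continuous nucleation: 4 in bulk mode,
        3 in surface mode.
    geometry : "bulk" or "surface"
    global_scale : float
        Multiplicative calibration factor applied to J.
    """

    nucleation_table: tuple[tuple[float, float], ...]
    growth_table: tuple[tuple[float, float], ...]
    geometry: str = "bulk"
    avrami_exponent: int | None = None
    global_scale: float = 1.0

    def __post_init__(self):
        if self.geometry not in _GEOMETRY_CONSTANTS:
            raise InvalidParameterError(f"unknown geometry {self.geometry!r}")
        n_expected = _GEOMETRY_CONSTANTS[self.geometry][1]
        if self.avrami_exponent is None:
            object.__setattr__(self, "avrami_exponent", n_expected)
        elif self.avrami_exponent != n_expected:
            raise InvalidParameterError(
                f"continuous nucleation in {self.geometry} geometry requires "
                f"Avrami exponent {n_expected}, got {self.avrami_exponent}"
            )
        if self.global_scale <= 0:
            raise InvalidParameterError("global_scale must be positive")
        for name, tab in (("nucleation", self.nucleation_table),
                          ("growth", self.growth_table)):
            T = np.array([row[0] for row in tab])
            if len(T) < 2 or np.any(np.diff(T) <= 0):
                raise InvalidParameterError(f"{name} table needs increasing T nodes")

    def _interp_log10(self, T, table) -> np.ndarray:
        tab = np.asarray(table, dtype=float)
        T = np.asarray(T, dtype=float)
        if np.any(T < tab[0, 0]) or np.any(T > tab[-1, 0]):
            warnings.warn(
                "temperature outside kinetics table range; clamping to endpoints",
                stacklevel=3,
            )
        return np.interp(T, tab[:, 0], tab[:, 1])


def nucleation_rate(T, params: KineticsParams) -> np.ndarray:
    """J(T): log-linear interpolation of the table times the global scale."""
    return params.global_scale * 10.0 ** params._interp_log10(T, params.nucleation_table)


def growth_rate(T, params: KineticsParams) -> np.ndarray:
    """u(T): log-linear interpolation of the growth table."""
    return 10.0 ** params._interp_log10(T, params.growth_table)


@dataclass(frozen=True)
class CrystallizationResult:
    """Crystalline fraction X(t) along a trajectory."""

    times: np.ndarray
    fraction: np.ndarray


def _active_rates(traj: ThermalTrajectory, params: KineticsParams):
    """J(t), u(t) along the trajectory, zeroed where crystallization is off.

    Crystallization is suppressed once the sample is fully molten and above
    the melting point (stable liquid), and trivially wherever J or u vanish.
    Temperatures are clamped to the table range silently here: along a
    trajectory the only excursions are into the suppressed stable-liquid
    region, where both rates are zeroed anyway.
    """
    T = np.asarray(traj.temperatures, dtype=float)
    suppressed = (np.asarray(traj.melt_fraction) >= 1.0) & (T > T_MELT)
    nuc = np.asarray(params.nucleation_table, dtype=float)
    gro = np.asarray(params.growth_table, dtype=float)
    J = params.global_scale * 10.0 ** np.interp(T, nuc[:, 0], nuc[:, 1])
    u = 10.0 ** np.interp(T, gro[:, 0], gro[:, 1])
    return np.where(suppressed, 0.0, J), np.where(suppressed, 0.0, u)


def _extended_volume_final(times, J, u, K: float, p: int) -> float:
    U = cumulative_trapezoid(u, times, initial=0.0)
    integrand = J * (U[-1] - U) ** p
    return K * float(np.trapezoid(integrand, times))


def crystallized_fraction(
    traj: ThermalTrajectory, params: KineticsParams
) -> CrystallizationResult:
    """Integrate the Avrami extended volume along a thermal trajectory.

    Returns X(t) on the trajectory's own time grid.  The double integral is
    evaluated with the trapezoidal rule; grains stop nucleating and growing
    in the fully molten state above the melting point.
    """
    times = np.asarray(traj.times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise InvalidParameterError("trajectory times must be strictly increasing")
    K, n = _GEOMETRY_CONSTANTS[params.geometry]
    p = n - 1
    J, u = _active_rates(traj, params)
    U = cumulative_trapezoid(u, times, initial=0.0)
    # growth path length from tau to t; negative (tau > t) clipped to zero,
    # so a full trapezoid along tau equals the prefix integral int_0^{t}
    growth = np.clip(U[:, None] - U[None, :], 0.0, None) ** p
    integrand = growth * J[None, :]
    ext = K * np.trapezoid(integrand, times, axis=1)
    X = 1.0 - np.exp(-ext)
    X = np.maximum.accumulate(np.clip(X, 0.0, 1.0))
    return CrystallizationResult(times=times, fraction=X)


def final_crystallized_fraction(traj: ThermalTrajectory, params: KineticsParams) -> float:
    """Final X of a trajectory without building the full X(t) curve (O(N))."""
    times = np.asarray(traj.times, dtype=float)
    K, n = _GEOMETRY_CONSTANTS[params.geometry]
    J, u = _active_rates(traj, params)
    ext = _extended_volume_final(times, J, u, K, n - 1)
    return float(1.0 - np.exp(-ext))


def ramp_trajectory(
    R: float,
    T_start: float = 100.0,
    T_end: float = 280.0,
    n_points: int = 2000,
    hold_duration: float = 1e-6,
) -> ThermalTrajectory:
    """Idealized linear heating ramp at rate R followed by a hold at T_end.

    Melting is treated as instantaneous at the melting point (no latent-heat
    plateau): the melt fraction steps to 1 where T exceeds 273.15 K, so the
    post-melt hold contributes no crystallization.
    """
    if R <= 0:
        raise InvalidParameterError("ramp rate must be positive")
    ramp_t = (T_end - T_start) / R
    t1 = np.linspace(0.0, ramp_t, n_points)
    T1 = T_start + R * t1
    t2 = ramp_t + np.linspace(0.0, hold_duration, max(8, n_points // 50))[1:]
    times = np.concatenate([t1, t2])
    T = np.concatenate([T1, np.full(len(t2), T_end)])
    melt = (T > T_MELT).astype(float)
    return ThermalTrajectory(times=times, temperatures=T, melt_fraction=melt)


def fraction_at_ramp_rate(
    R: float,
    params: KineticsParams,
    T_start: float = 100.0,
    T_end: float = 280.0,
    n_points: int = 2000,
) -> float:
    """Final crystalline fraction of a linear ramp at heating rate R."""
    traj = ramp_trajectory(R, T_start, T_end, n_points)
    return final_crystallized_fraction(traj, params)


def critical_heating_rate(
    params: KineticsParams,
    X_threshold: float = 0.01,
    rate_bounds: tuple[float, float] = (1e4, 1e12),
    rel_tol: float = 0.01,
    **ramp_kwargs,
) -> float:
    """Heating rate at which the final ramp fraction equals the threshold.

    The final fraction is strictly decreasing in the ramp rate, so the
    critical rate is found by root bracketing on log10(R) to ``rel_tol``
    relative precision.
    """
    if not (0 < X_threshold < 1):
        raise InvalidParameterError("X_threshold must be in (0, 1)")
    lo, hi = rate_bounds

    def f(log_R):
        return fraction_at_ramp_rate(10.0 ** log_R, params, **ramp_kwargs) - X_threshold

    f_lo, f_hi = f(np.log10(lo)), f(np.log10(hi))
    if f_lo < 0 or f_hi > 0:
        raise SearchFailureError(
            f"threshold {X_threshold} not bracketed in [{lo:g}, {hi:g}] K/s "
            f"(X at bounds: {f_lo + X_threshold:.3g}, {f_hi + X_threshold:.3g})"
        )
    log_rc = brentq(f, np.log10(lo), np.log10(hi), xtol=np.log10(1.0 + rel_tol) / 2)
    return float(10.0 ** log_rc)


def rate_ratio_for_nucleation_factor(f: float, n: float = 4) -> float:
    """Critical-rate scaling factor for a nucleation rate scaled by ``f``.

    Under a pure linear ramp the Avrami extended volume scales as
    ``scale / R^n``, so multiplying J by ``f`` multiplies the critical heating
    rate by ``f**(1/n)``.  With n = 4 a five-fold nucleation-rate difference
    maps to a 5**(1/4) = 1.495 ≈ 1.5-fold critical-rate difference.
    """
    if f <= 0:
        raise InvalidParameterError("factor must be positive")
    if n < 1:
        raise InvalidParameterError("Avrami exponent must be >= 1")
    return float(f ** (1.0 / n))


# ---------------------------------------------------------------------------
# Default tables
# ---------------------------------------------------------------------------

def default_kinetics(
    geometry: str = "bulk",
    anchor_rate: float = 1e8,
    anchor_threshold: float = 0.01,
) -> KineticsParams:
    """Default J(T), u(T) tables with the absolute scale calibrated.

    Shapes follow the qualitative physics of supercooled water: a
    single-peaked nucleation rate maximal near 205 K that collapses toward
    the melting point, and a growth speed that surges with temperature
    through the nucleation zone but is throttled by the vanishing
    thermodynamic driving force on approach to the melting point (a crystal
    in contact with its melt at equilibrium cannot grow; without this taper
    any dwell at the melting plateau would crystallize the sample at every
    heating rate).  The absolute scale of J is not measurable here, so the
    ``global_scale`` is fixed by one anchor: the critical heating rate at the
    given threshold equals ``anchor_rate``.  Because the ramp extended volume
    is linear in J, the calibration is a single closed-form rescaling.
    """
    T = np.concatenate(
        [np.arange(100.0, 268.0, 4.0), [268.0, 270.0, 271.5, 272.5, 273.0],
         [T_MELT, 280.0]]
    )
    log10_J = np.where(
        T < T_MELT, 21.0 - 6.0 * ((T - 205.0) / 30.0) ** 2, -30.0
    )
    # growth speed = mobility (VFT-like, frozen out toward the glass
    # transition) x undercooling driving force (vanishing at the melting
    # point); the product peaks near 247 K at ~0.2 m/s, the familiar shape of
    # ice-growth velocity in supercooled water
    mobility = 1.8 - 460.0 / np.maximum(T - 118.0, 1.0)
    driving = -np.expm1(-(T_MELT - T) / 26.0)
    log10_u = np.where(
        driving > 0, mobility + np.log10(np.maximum(driving, 1e-300)), -15.0
    )
    params = KineticsParams(
        nucleation_table=tuple(zip(T, log10_J)),
        growth_table=tuple(zip(T, log10_u)),
        geometry=geometry,
        global_scale=1.0,
    )
    traj = ramp_trajectory(anchor_rate)
    K, n = _GEOMETRY_CONSTANTS[geometry]
    J, u = _active_rates(traj, params)
    ext_unit = _extended_volume_final(np.asarray(traj.times), J, u, K, n - 1)
    target_ext = -np.log1p(-anchor_threshold)
    return replace(params, global_scale=target_ext / ext_unit)
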