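"""TOML configuration loading for the command-line workflow.

A single TOML file holds per-stage sections; every section is optional and
falls back to the package defaults, so a minimal run needs no config at all.

Recognized sections::

    [pulse]      total_duration_s, spike_multiplier, spike_duration_s
    [thermal]    plateau_K, rise_time_to_273K_s, bath_K, latent_heat_J_per_g
    [kinetics]   geometry, table_csv, global_scale, threshold
    [scan]       heating_rates_K_per_s, probe_window_s, replicates, noise,
                 seed, exposure
    [decompose]  fit_q_min, fit_q_max
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics as kin
from .pulse_thermal import PulseShape, ThermalParams, build_pulse, calibrate_thermal
from .synthetic import ScanConfig


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def pulse_from_config(cfg: dict) -> PulseShape:
    sec = cfg.get("pulse", {})
    return build_pulse(
        hold_power_multiple=sec.get("hold_power_multiple", 1.0),
        total_duration=sec.get("total_duration_s", 30e-6),
        spike_multiplier=sec.get("spike_multiplier", 1.0),
        spike_duration=sec.get("spike_duration_s", 0.0),
    )


def thermal_from_config(cfg: dict) -> ThermalParams:
    sec = cfg.get("thermal", {})
    return calibrate_thermal(
        plateau=sec.get("plateau_K", 280.0),
        rise_time_to_273K=sec.get("rise_time_to_273K_s", 11e-6),
        bath=sec.get("bath_K", 100.0),
        latent_heat_fusion=sec.get("latent_heat_J_per_g", 334.0),
    )


def kinetics_from_config(cfg: dict) -> kin.KineticsParams:
    sec = cfg.get("kinetics", {})
    geometry = sec.get("geometry", "bulk")
    if "table_csv" in sec:
        df = pd.read_csv(sec["table_csv"])
        params = kin.KineticsParams(
            nucleation_table=tuple(zip(df["T_K"], df["log10_J"])),
            growth_table=tuple(zip(df["T_K"], df["log10_u"])),
            geometry=geometry,
            global_scale=sec.get("global_scale", 1.0),
        )
        return params
    return kin.default_kinetics(geometry=geometry)


def scan_from_config(cfg: dict, seed: int | None = None) -> ScanConfig:
    sec = cfg.get("scan", {})
    rates = sec.get("heating_rates_K_per_s")
    kwargs = {}
    if rates is not None:
        kwargs["heating_rates"] = tuple(float(r) for r in rates)
    if seed is None:
        seed = sec.get("seed", 0)
    return ScanConfig(
        probe_window=sec.get("probe_window_s", 10e-6),
        replicates=sec.get("replicates", 5),
        noise=sec.get("noise", True),
        seed=seed,
        exposure=sec.get("exposure", 1.0),
        **kwargs,
    )


def fit_range_from_config(cfg: dict) -> tuple[float, float]:
    sec = cfg.get("decompose", {})
    return (sec.get("fit_q_min", 0.8), sec.get("fit_q_max", 3.5))


def trajectory_to_frame(traj) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": np.asarray(traj.times),
            "temperature_K": np.asarray(traj.temperatures),
            "melt_fraction": np.asarray(traj.melt_fraction),
        }
    )
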