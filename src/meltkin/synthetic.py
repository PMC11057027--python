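"""Synthetic heating-rate-scan datasets with the statistics the analysis assumes.

One synthetic experiment emulates a flash-melting measurement: a shaped laser
pulse heats the sample at a chosen average rate, crystallization is integrated
along the simulated trajectory, and a probe pulse time-averages the sample
state over its window (default the first 10 us of melting), so the recorded
pattern is a mixture of the three reference structures.  Replicates differ
only in their Poisson noise realization, mirroring repeated exposures summed
together in the real experiment.

The default scan covers average heating rates from 1.6e7 to 3.0e8 K/s — the
span reachable by varying the leading-spike intensity of a 30 us pulse — with
5 replicates per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import kinetics as kin
from .decomposition import COMPONENT_NAMES
from .diffraction import BasisSet, DiffractionProfile, default_basis, liquid_blend_weight
from .errors import DatasetFormatError, SearchFailureError
from .pulse_thermal import (
    ThermalParams,
    average_heating_rate,
    build_pulse,
    calibrate_thermal,
    simulate_temperature,
)


@dataclass(frozen=True)
class ScanConfig:
    """Study design of a synthetic heating-rate scan."""

    heating_rates: tuple[float, ...] = tuple(np.geomspace(1.6e7, 3.0e8, 8))
    probe_window: float = 10e-6
    replicates: int = 5
    noise: bool = True
    seed: int = 0
    pulse_duration: float = 30e-6
    spike_duration: float = 450e-9
    exposure: float = 0.5

    def __post_init__(self):
        R = np.asarray(self.heating_rates, dtype=float)
        if np.any(R <= 0) or np.any(np.diff(R) <= 0):
            raise DatasetFormatError("heating rates must be positive and increasing")
        if self.replicates < 1 or self.probe_window <= 0:
            raise DatasetFormatError("need replicates >= 1 and a positive probe window")


@dataclass(frozen=True)
class ScanCondition:
    """One heating-rate condition: ground truth plus replicate profiles."""

    heating_rate: float
    spike_multiplier: float
    true_weights: dict
    clean_profile: DiffractionProfile
    replicate_profiles: tuple[DiffractionProfile, ...]


@dataclass(frozen=True)
class SyntheticScan:
    config: ScanConfig
    conditions: tuple[ScanCondition, ...]

    def as_inputs(self, summed: bool = True) -> list[tuple[float, DiffractionProfile]]:
        """(rate, profile) pairs for the decomposition stage.

        ``summed`` sums the replicates per condition, as the experimental
        azimuthal averages are produced from the sum of all exposures.
        """
        from .diffraction import sum_replicates

        out = []
        for c in self.conditions:
            prof = sum_replicates(list(c.replicate_profiles)) if summed else c.clean_profile
            out.append((c.heating_rate, prof))
        return out


def find_spike_multiplier(
    target_rate: float,
    params: ThermalParams,
    pulse_duration: float = 30e-6,
    spike_duration: float = 450e-9,
    bracket: tuple[float, float] = (1.0, 64.0),
) -> float:
    """Spike multiplier whose pulse realizes a given 100->273 K average rate.

    The spike duration is held fixed; the average heating rate is strictly
    increasing in the multiplier, so the root is bracketed and solved
    directly.
    """

    def rate_of(mult: float) -> float:
        pulse = build_pulse(1.0, pulse_duration, mult, spike_duration)
        traj = simulate_temperature(pulse, params, t_max=min(12e-6, pulse_duration))
        return average_heating_rate(traj).rate

    lo, hi = bracket
    r_lo = rate_of(lo)
    if target_rate <= r_lo * (1.0 + 1e-6):
        if target_rate < r_lo * (1.0 - 0.02):
            raise SearchFailureError(
                f"rate {target_rate:.3g} K/s below the rectangular-pulse rate "
                f"{r_lo:.3g} K/s"
            )
        return lo
    if target_rate > rate_of(hi):
        raise SearchFailureError(
            f"rate {target_rate:.3g} K/s unattainable below multiplier {hi}"
        )
    return float(brentq(lambda m: rate_of(m) - target_rate, lo, hi, xtol=1e-3))


DEFAULT_SPIKE_EXCESS = 16.5 * 450e-9
"""Spike excess fluence shared by the shaped pulses, hold-power x seconds.

Matches the most intense pulse of the family (17.5x hold power for 450 ns);
the heating rate is tuned by trading spike intensity against duration while
keeping this integral constant, exactly as the experimental pulse shapes do.
"""


def find_pulse_for_rate(
    target_rate: float,
    params: ThermalParams,
    pulse_duration: float = 30e-6,
    spike_excess: float = DEFAULT_SPIKE_EXCESS,
    min_duration: float = 50e-9,
):
    """Shaped pulse from the constant-integral family realizing a target rate.

    The family consists of the plain rectangular pulse (lowest rate) and
    leading spikes with a fixed excess fluence ``(m - 1) d = spike_excess``:
    shortening the spike while raising its intensity increases the average
    100->273 K heating rate monotonically.  Rates between the rectangular
    pulse and the longest admissible spike are realized by shrinking the
    spike integral at maximal duration.

    Returns ``(pulse, spike_multiplier, spike_duration)``.
    """
    max_duration = 0.95 * pulse_duration

    def pulse_with_duration(d: float):
        return build_pulse(1.0, pulse_duration, 1.0 + spike_excess / d, d)

    def pulse_with_multiplier(m: float):
        return build_pulse(1.0, pulse_duration, m, max_duration)

    def rate_of(pulse) -> float:
        # the 273 K crossing always falls inside the rectangular rise time
        traj = simulate_temperature(pulse, params, t_max=min(12e-6, pulse_duration))
        return average_heating_rate(traj).rate

    rect = build_pulse(1.0, pulse_duration)
    r_rect = rate_of(rect)
    if target_rate <= r_rect * (1.0 + 1e-6):
        if target_rate < r_rect * (1.0 - 0.05):
            raise SearchFailureError(
                f"rate {target_rate:.3g} K/s below the rectangular-pulse rate "
                f"{r_rect:.3g} K/s"
            )
        return rect, 1.0, 0.0
    r_slow = rate_of(pulse_with_duration(max_duration))
    if target_rate > r_slow:
        # constant-integral branch: rate decreasing in spike duration
        if target_rate > rate_of(pulse_with_duration(min_duration)):
            raise SearchFailureError(
                f"rate {target_rate:.3g} K/s unattainable with spikes of "
                f">= {min_duration:g} s at excess fluence {spike_excess:g}"
            )
        d = brentq(
            lambda logd: rate_of(pulse_with_duration(10.0 ** logd)) - target_rate,
            np.log10(min_duration), np.log10(max_duration), xtol=5e-4,
        )
        d = float(10.0 ** d)
        return pulse_with_duration(d), 1.0 + spike_excess / d, d
    # reduced-integral branch: long weak spike, rate increasing in multiplier
    m_hi = 1.0 + spike_excess / max_duration
    m = brentq(
        lambda m: rate_of(pulse_with_multiplier(m)) - target_rate,
        1.0, m_hi, xtol=1e-4,
    )
    return pulse_with_multiplier(float(m)), float(m), max_duration


def _window_weights(traj, kinetics: kin.KineticsParams, probe_window: float):
    """Probe-window time-averaged mixture weights (low, high, crystalline).

    At every instant the sample is a mixture of crystal (fraction X) and
    liquid (1 - X), the liquid split between the low- and high-temperature
    structures by the temperature blend weight; the probe averages these
    coefficients uniformly over its window.
    """
    mask = traj.times <= probe_window
    times = traj.times[mask]
    X = kin.crystallized_fraction(traj, kinetics).fraction[mask]
    alpha = liquid_blend_weight(traj.temperatures[mask])
    w_high_t = (1.0 - X) * alpha
    w_low_t = (1.0 - X) * (1.0 - alpha)
    span = times[-1] - times[0]
    w = np.array(
        [
            np.trapezoid(w_low_t, times) / span,
            np.trapezoid(w_high_t, times) / span,
            np.trapezoid(X, times) / span,
        ]
    )
    return dict(zip(COMPONENT_NAMES, map(float, w)))


def generate_scan(
    config: ScanConfig,
    thermal: ThermalParams | None = None,
    kinetics: kin.KineticsParams | None = None,
    basis: BasisSet | None = None,
) -> SyntheticScan:
    """Generate a full synthetic heating-rate scan.

    For each requested rate the spike multiplier is solved for on the thermal
    model, temperature and crystalline fraction are simulated, probe-window
    averaged mixture weights are formed, and replicate profiles are drawn
    with Poisson counting noise from deterministically spawned sub-seeds.
    """
    thermal = thermal or calibrate_thermal()
    kinetics = kinetics or kin.default_kinetics()
    basis = basis or default_basis()
    root_seq = np.random.SeedSequence(config.seed)
    cond_seqs = root_seq.spawn(len(config.heating_rates))

    conditions = []
    for rate, seq in zip(config.heating_rates, cond_seqs):
        pulse, mult, _ = find_pulse_for_rate(rate, thermal, config.pulse_duration)
        traj = simulate_temperature(pulse, thermal, t_max=config.probe_window * 1.02)
        weights = _window_weights(traj, kinetics, config.probe_window)
        clean = DiffractionProfile(
            q=basis.q,
            intensity=config.exposure * (basis.matrix() @ np.array(
                [weights[name] for name in COMPONENT_NAMES]
            )),
            label=f"rate_{rate:.3g}",
        )
        reps = []
        for i, rep_seq in enumerate(seq.spawn(config.replicates)):
            if config.noise:
                rng = np.random.default_rng(rep_seq)
                intensity = rng.poisson(clean.intensity).astype(float)
            else:
                intensity = clean.intensity.copy()
            reps.append(
                DiffractionProfile(q=basis.q, intensity=intensity,
                                   label=f"{clean.label}_rep{i}")
            )
        conditions.append(
            ScanCondition(
                heating_rate=float(rate),
                spike_multiplier=float(mult),
                true_weights=weights,
                clean_profile=clean,
                replicate_profiles=tuple(reps),
            )
        )
    return SyntheticScan(config=config, conditions=tuple(conditions))


def true_threshold_crossing(scan: SyntheticScan, threshold: float = 0.01) -> float:
    """Heating rate at which the generator's true crystalline weight hits a threshold.

    Interpolates the ground-truth probe-window-averaged crystalline weight
    log-log in heating rate, on the decaying branch (from the empirical
    maximum onwards).  This is the critical rate the scan actually encodes;
    analysis recovery is judged against it.
    """
    R = np.array([c.heating_rate for c in scan.conditions])
    w = np.array([c.true_weights["crystalline"] for c in scan.conditions])
    i0 = int(np.argmax(w))
    R, w = R[i0:], np.maximum(w[i0:], 1e-300)
    if len(R) < 2 or not (w[-1] < threshold < w[0]):
        raise SearchFailureError(
            f"threshold {threshold} not crossed by the scan's true weights"
        )
    return float(np.exp(np.interp(np.log(threshold), np.log(w[::-1]), np.log(R[::-1]))))


# ---------------------------------------------------------------------------
# Dataset persistence
# ---------------------------------------------------------------------------

def write_dataset(scan: SyntheticScan, directory: str | Path) -> Path:
    """Write a scan as manifest CSV + per-replicate profile CSVs + truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {"config": _config_dict(scan.config), "conditions": []}
    for ci, cond in enumerate(scan.conditions):
        _write_profile(cond.clean_profile, directory / f"profile_c{ci:02d}_clean.csv")
        for ri, prof in enumerate(cond.replicate_profiles):
            rel = f"profile_c{ci:02d}_r{ri:02d}.csv"
            _write_profile(prof, directory / rel)
            rows.append(
                {"rate_K_per_s": cond.heating_rate, "replicate": ri, "profile_path": rel}
            )
        truth["conditions"].append(
            {
                "heating_rate_K_per_s": cond.heating_rate,
                "spike_multiplier": cond.spike_multiplier,
                "true_weights": cond.true_weights,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return directory


def read_dataset(directory: str | Path) -> SyntheticScan:
    """Exact inverse of :func:`write_dataset`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise DatasetFormatError(f"missing manifest: {manifest_path}")
    truth_path = directory / "ground_truth.json"
    if not truth_path.exists():
        raise DatasetFormatError(f"missing ground truth: {truth_path}")
    try:
        truth = json.loads(truth_path.read_text())
        config = ScanConfig(
            heating_rates=tuple(truth["config"]["heating_rates"]),
            probe_window=truth["config"]["probe_window"],
            replicates=truth["config"]["replicates"],
            noise=truth["config"]["noise"],
            seed=truth["config"]["seed"],
            pulse_duration=truth["config"]["pulse_duration"],
            spike_duration=truth["config"]["spike_duration"],
            exposure=truth["config"]["exposure"],
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise DatasetFormatError(f"corrupted ground-truth file {truth_path}: {exc}") from exc
    manifest = pd.read_csv(manifest_path, float_precision="round_trip")
    conditions = []
    for ci, cond_truth in enumerate(truth["conditions"]):
        rate = cond_truth["heating_rate_K_per_s"]
        sel = manifest[np.isclose(manifest["rate_K_per_s"], rate)]
        reps = tuple(
            _read_profile(directory / row.profile_path)
            for row in sel.sort_values("replicate").itertuples()
        )
        clean = _read_profile(directory / f"profile_c{ci:02d}_clean.csv")
        conditions.append(
            ScanCondition(
                heating_rate=rate,
                spike_multiplier=cond_truth["spike_multiplier"],
                true_weights=cond_truth["true_weights"],
                clean_profile=clean,
                replicate_profiles=reps,
            )
        )
    return SyntheticScan(config=config, conditions=tuple(conditions))


def _config_dict(config: ScanConfig) -> dict:
    return {
        "heating_rates": [float(r) for r in config.heating_rates],
        "probe_window": config.probe_window,
        "replicates": config.replicates,
        "noise": config.noise,
        "seed": config.seed,
        "pulse_duration": config.pulse_duration,
        "spike_duration": config.spike_duration,
        "exposure": config.exposure,
    }


def _write_profile(profile: DiffractionProfile, path: Path) -> None:
    pd.DataFrame({"q_invA": profile.q, "intensity": profile.intensity}).to_csv(
        path, index=False, float_format="%.17g"
    )


def _read_profile(path: Path) -> DiffractionProfile:
    if not path.exists():
        raise DatasetFormatError(f"missing profile file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    return DiffractionProfile(
        q=df["q_invA"].to_numpy(), intensity=df["intensity"].to_numpy(), label=path.stem
    )
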