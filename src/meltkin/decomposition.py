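"""Non-negative spectral decomposition of diffraction profiles and trend fits.

Each measured (or synthesized) radial profile is modelled as a non-negative
linear combination of the three reference components — low-temperature
liquid, high-temperature liquid, crystalline — fitted by non-negative least
squares over a restricted q window.  The weights are deliberately not
constrained to sum to one, because recorded intensities scale with exposure;
normalized weights are reported alongside.

Across a heating-rate scan the component weights follow smooth trends: the
crystalline weight decays with heating rate and its decay curve, summarized
by an exponential fit w(R) = a exp(-R / rho) + c, defines the critical
heating rate as the rate where the fitted weight drops to a small threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .diffraction import BasisSet, DiffractionProfile
from .errors import ConditioningError, InvalidParameterError, NotAttainableError

COMPONENT_NAMES = ("low_T", "high_T", "crystalline")
DEFAULT_FIT_RANGE = (0.8, 3.5)


@dataclass(frozen=True)
class DecompositionResult:
    """NNLS weights of the three components with their standard errors."""

    weights: np.ndarray
    std_errors: np.ndarray
    residual_norm: float

    @property
    def normalized_weights(self) -> np.ndarray:
        s = float(np.sum(self.weights))
        return self.weights / s if s > 0 else self.weights

    def as_dict(self) -> dict:
        return {
            "weights": dict(zip(COMPONENT_NAMES, map(float, self.weights))),
            "std_errors": dict(zip(COMPONENT_NAMES, map(float, self.std_errors))),
            "normalized_weights": dict(
                zip(COMPONENT_NAMES, map(float, self.normalized_weights))
            ),
            "residual_norm": float(self.residual_norm),
        }


def decompose(
    profile: DiffractionProfile,
    basis: BasisSet,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    poisson_weights: bool = True,
) -> DecompositionResult:
    """Fit a profile as a non-negative weighted sum of the basis components.

    The basis is resampled onto the profile's q grid by linear interpolation
    if the grids differ.  With ``poisson_weights`` (the default) the system
    is whitened by the counting-noise standard deviation: a first pass
    weighted by the observed counts, then one reweighting step using the
    model-predicted counts, which avoids the low-count bias of purely
    observed-count variances.  Standard errors come from the unconstrained
    linear-model covariance at the NNLS solution, with the residual variance
    estimated from the fit residuals and the number of active components.
    """
    lo, hi = fit_range
    mask = (profile.q >= lo) & (profile.q <= hi)
    if mask.sum() < 4:
        raise InvalidParameterError(f"empty or degenerate fit range {fit_range}")
    q = profile.q[mask]
    b = profile.intensity[mask]
    if len(basis.q) == len(profile.q) and np.allclose(basis.q, profile.q):
        A = basis.matrix()[mask]
    else:
        A = np.column_stack([c.interpolate(q) for c in basis.components()])
    if poisson_weights:
        s = np.sqrt(np.maximum(b, 1.0))
        w1, _ = optimize.nnls(A / s[:, None], b / s)
        s = np.sqrt(np.maximum(A @ w1, 1.0))
        Aw, bw = A / s[:, None], b / s
    else:
        Aw, bw = A, b
    cond = np.linalg.cond(Aw)
    if cond >= basis.max_condition:
        raise ConditioningError(
            f"basis condition number {cond:.3g} on the fit range is too high"
        )
    w, rnorm = optimize.nnls(Aw, bw)
    n_active = max(int(np.sum(w > 0)), 1)
    dof = max(len(b) - n_active, 1)
    sigma2 = rnorm**2 / dof
    cov = sigma2 * np.linalg.pinv(Aw.T @ Aw)
    return DecompositionResult(
        weights=w, std_errors=np.sqrt(np.diag(cov)), residual_norm=float(rnorm)
    )


@dataclass(frozen=True)
class ExponentialTrend:
    """Exponential-decay trend w(R) = amplitude * exp(-R / rate_scale) + offset."""

    amplitude: float
    rate_scale: float
    offset: float

    def __post_init__(self):
        if self.rate_scale <= 0:
            raise InvalidParameterError("rate_scale must be positive")

    def evaluate(self, R) -> np.ndarray:
        R = np.asarray(R, dtype=float)
        return self.amplitude * np.exp(-R / self.rate_scale) + self.offset


def fit_trend(
    rates: np.ndarray,
    weights: np.ndarray,
    nonnegative: bool = False,
    sigma: np.ndarray | None = None,
) -> ExponentialTrend:
    """Least-squares exponential trend of a component weight versus rate.

    ``nonnegative`` constrains both amplitude and offset to be >= 0, as
    appropriate for the crystalline weight; leave it off for components whose
    weight grows with heating rate (negative amplitude).  ``sigma`` supplies
    per-point standard errors for a weighted fit.
    """
    R = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(R) < 4:
        raise InvalidParameterError("need at least 4 points to fit a trend")
    if np.any(R <= 0):
        raise InvalidParameterError("rates must be positive")
    scale = float(np.median(R))
    x = R / scale
    if np.ptp(w) <= 1e-12 * (np.abs(w).max() + 1.0):
        return ExponentialTrend(0.0, scale, float(np.mean(w)))

    def model(x, a, rho, c):
        return a * np.exp(-x / rho) + c

    a0 = w[np.argmin(R)] - w[np.argmax(R)]
    c0 = w[np.argmax(R)]
    if nonnegative:
        a0, c0 = max(a0, 1e-6), max(c0, 0.0)
        bounds = ([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf])
    else:
        bounds = ([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf])
    if sigma is not None:
        sigma = np.maximum(np.asarray(sigma, dtype=float), 1e-6 * max(np.abs(w).max(), 1e-12))
    try:
        popt, _ = optimize.curve_fit(
            model, x, w, p0=[a0, 1.0, c0], bounds=bounds, sigma=sigma, maxfev=20000
        )
    except RuntimeError as exc:
        raise InvalidParameterError(f"trend fit did not converge: {exc}") from exc
    a, rho, c = popt
    return ExponentialTrend(float(a), float(rho * scale), float(c))


def critical_rate_from_trend(trend: ExponentialTrend, threshold: float) -> float:
    """Heating rate at which the fitted trend crosses the threshold.

    Analytic inversion of the exponential model:
    ``R_c = rate_scale * ln(amplitude / (threshold - offset))``.
    """
    if trend.amplitude <= 0:
        raise NotAttainableError("trend has no decaying component (amplitude <= 0)")
    if threshold <= trend.offset:
        raise NotAttainableError(
            f"threshold {threshold} never reached: trend offset is {trend.offset}"
        )
    return float(trend.rate_scale * np.log(trend.amplitude / (threshold - trend.offset)))


@dataclass(frozen=True)
class RateScan:
    """Decomposition results along a heating-rate scan."""

    heating_rates: np.ndarray
    profiles: tuple[DiffractionProfile, ...]
    results: tuple[DecompositionResult, ...]

    def __post_init__(self):
        R = np.asarray(self.heating_rates, dtype=float)
        if np.any(np.diff(R) <= 0):
            raise InvalidParameterError("heating rates must be strictly increasing")

    def weight_matrix(self, normalized: bool = True) -> np.ndarray:
        """(n_rates, 3) array of component weights."""
        return np.array(
            [r.normalized_weights if normalized else r.weights for r in self.results]
        )


@dataclass(frozen=True)
class ScanAnalysis:
    """Full scan decomposition with per-component trends and the critical rate."""

    scan: RateScan
    trends: dict
    critical_rate: float | None

    def as_dict(self) -> dict:
        return {
            "heating_rates_K_per_s": [float(r) for r in self.scan.heating_rates],
            "results": [r.as_dict() for r in self.scan.results],
            "trends": {
                name: {
                    "amplitude": t.amplitude,
                    "rate_scale_K_per_s": t.rate_scale,
                    "offset": t.offset,
                }
                for name, t in self.trends.items()
            },
            "critical_rate_K_per_s": self.critical_rate,
        }


def analyze_scan(
    scan_inputs: list[tuple[float, DiffractionProfile]],
    basis: BasisSet,
    threshold: float = 0.01,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
) -> ScanAnalysis:
    """Decompose a heating-rate scan and extract the critical heating rate.

    Decomposes every profile, fits exponential trends to the normalized
    weights of all three components (non-negative amplitude and offset for
    the crystalline one), and inverts the crystalline trend at the threshold.
    If the crystalline signal is absent everywhere the critical rate is
    reported as ``None``.

    The crystalline decay is fitted from the empirical weight maximum
    onwards, weighted by the decomposition standard errors.  At rates slow
    enough to crystallize the sample completely, the probe-window-averaged
    weight reflects when crystallization finishes inside the window rather
    than how much forms, and can rise with heating rate; that saturated
    branch carries no information about the decay the exponential describes.
    """
    if len(scan_inputs) < 4:
        raise InvalidParameterError("need at least 4 scan points")
    order = np.argsort([r for r, _ in scan_inputs])
    rates = np.array([scan_inputs[i][0] for i in order], dtype=float)
    profiles = tuple(scan_inputs[i][1] for i in order)
    results = tuple(decompose(p, basis, fit_range) for p in profiles)
    scan = RateScan(heating_rates=rates, profiles=profiles, results=results)
    W = scan.weight_matrix(normalized=True)
    sums = np.array([max(np.sum(r.weights), 1e-300) for r in results])
    SE = np.array([r.std_errors for r in results]) / sums[:, None]
    i0 = int(np.argmax(W[:, 2]))
    if len(rates) - i0 < 4:
        i0 = max(len(rates) - 4, 0)
    trends = {
        "low_T": fit_trend(rates, W[:, 0]),
        "high_T": fit_trend(rates, W[:, 1]),
        "crystalline": fit_trend(
            rates[i0:], W[i0:, 2], nonnegative=True, sigma=SE[i0:, 2]
        ),
    }
    try:
        rc = critical_rate_from_trend(trends["crystalline"], threshold)
    except NotAttainableError:
        rc = None
    return ScanAnalysis(scan=scan, trends=trends, critical_rate=rc)
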