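"""Synthetic electron-diffraction profiles, ring images, and azimuthal averaging.

Three reference structures span the states a flash-melted amorphous-ice film
explores: the low-temperature amorphous/deeply supercooled liquid (HGW-like,
~100 K), the high-temperature liquid near its plateau (~280 K), and stacking
disordered ice carrying narrow Bragg rings.  On heating, the first broad
diffraction maximum of the liquid shifts to higher momentum transfer while
the second one moves slightly the other way, which is what the default peak
positions encode.

Reference profiles are parametric — Gaussian peaks on a smooth decaying
background — standing in for recorded reference patterns; positions and
widths are configurable.  Bragg-ring positions for the crystalline component
come from q = 2 pi / d with hexagonal-ice lattice constants a = 4.52 A,
c = 7.36 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConditioningError, InvalidParameterError

LOW_T_REF = 100.0
HIGH_T_REF = 280.0


@dataclass(frozen=True)
class DiffractionProfile:
    """Azimuthally averaged intensity versus momentum transfer.

    ``q`` is in inverse Angstrom and must be strictly increasing; intensities
    are mean detector counts and must be nonnegative.
    """

    q: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.intensity, dtype=float)
        if q.ndim != 1 or len(q) != len(I):
            raise InvalidParameterError("q and intensity must be 1-D and equal length")
        if np.any(np.diff(q) <= 0) or q[0] <= 0:
            raise InvalidParameterError("q grid must be positive and strictly increasing")
        if np.any(I < 0):
            raise InvalidParameterError("intensity must be nonnegative")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", I)

    def interpolate(self, q_new: np.ndarray) -> np.ndarray:
        return np.interp(q_new, self.q, self.intensity)

    def first_maximum(self) -> float:
        """q position of the global intensity maximum."""
        return float(self.q[int(np.argmax(self.intensity))])


@dataclass(frozen=True)
class PeakModel:
    """Gaussian peaks (center, amplitude, sigma) on an exponential background."""

    peaks: tuple[tuple[float, float, float], ...]
    background_amplitude: float = 0.0
    background_decay: float = 1.2

    def evaluate(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        out = self.background_amplitude * np.exp(-q / self.background_decay)
        for center, amp, sigma in self.peaks:
            out = out + amp * np.exp(-0.5 * ((q - center) / sigma) ** 2)
        return out


# Bragg ring positions q = 2 pi / d for hexagonal ice (a = 4.52 A, c = 7.36 A):
# (100) d = a sqrt(3)/2, (002) d = c/2, (101), plus two higher-order rings.
_Q_100 = 2.0 * np.pi / (4.52 * np.sqrt(3.0) / 2.0)   # 1.605
_Q_002 = 2.0 * np.pi / (7.36 / 2.0)                  # 1.707
_Q_101 = 2.0 * np.pi / 3.45                          # 1.821
_Q_110 = 2.0 * np.pi / (4.52 / 2.0)                  # 2.780
_Q_103 = 2.0 * np.pi / 1.92                          # 3.272

DEFAULT_PEAK_MODELS: dict[str, PeakModel] = {
    "low_T": PeakModel(
        peaks=((1.70, 1000.0, 0.16), (3.05, 380.0, 0.28)),
        background_amplitude=400.0,
    ),
    "high_T": PeakModel(
        peaks=((2.00, 820.0, 0.26), (2.90, 300.0, 0.30)),
        background_amplitude=400.0,
    ),
    "crystalline": PeakModel(
        peaks=(
            (1.70, 500.0, 0.18),            # residual amorphous hump
            (3.00, 200.0, 0.30),
            (_Q_100, 900.0, 0.025),
            (_Q_002, 1000.0, 0.025),
            (_Q_101, 700.0, 0.025),
            (_Q_110, 350.0, 0.03),
            (_Q_103, 300.0, 0.03),
        ),
        background_amplitude=400.0,
    ),
}


def default_q_grid(n: int = 400, q_min: float = 0.2, q_max: float = 4.0) -> np.ndarray:
    return np.linspace(q_min, q_max, n)


def basis_profile(
    kind: str,
    q_grid: np.ndarray | None = None,
    shape_params: PeakModel | None = None,
) -> DiffractionProfile:
    """Reference profile of one mixture component on the given q grid."""
    if q_grid is None:
        q_grid = default_q_grid()
    if shape_params is None:
        if kind not in DEFAULT_PEAK_MODELS:
            raise InvalidParameterError(
                f"unknown profile kind {kind!r}; expected one of "
                f"{sorted(DEFAULT_PEAK_MODELS)}"
            )
        shape_params = DEFAULT_PEAK_MODELS[kind]
    return DiffractionProfile(
        q=np.asarray(q_grid, dtype=float),
        intensity=shape_params.evaluate(q_grid),
        label=kind,
    )


@dataclass(frozen=True)
class BasisSet:
    """The three reference profiles used for spectral decomposition.

    All three must share one q grid and be well separated: the condition
    number of the 3-column basis matrix must stay below ``max_condition``.
    """

    low_T: DiffractionProfile
    high_T: DiffractionProfile
    crystalline: DiffractionProfile
    max_condition: float = 1e6

    def __post_init__(self):
        for other in (self.high_T, self.crystalline):
            if len(other.q) != len(self.low_T.q) or not np.allclose(other.q, self.low_T.q):
                raise InvalidParameterError("basis profiles must share one q grid")
        cond = np.linalg.cond(self.matrix())
        if cond >= self.max_condition:
            raise ConditioningError(
                f"basis condition number {cond:.3g} exceeds {self.max_condition:g}"
            )

    @property
    def q(self) -> np.ndarray:
        return self.low_T.q

    def matrix(self) -> np.ndarray:
        """(n_q, 3) basis matrix in component order (low_T, high_T, crystalline)."""
        return np.column_stack(
            [self.low_T.intensity, self.high_T.intensity, self.crystalline.intensity]
        )

    def components(self) -> tuple[DiffractionProfile, ...]:
        return (self.low_T, self.high_T, self.crystalline)


def default_basis(q_grid: np.ndarray | None = None) -> BasisSet:
    if q_grid is None:
        q_grid = default_q_grid()
    return BasisSet(
        low_T=basis_profile("low_T", q_grid),
        high_T=basis_profile("high_T", q_grid),
        crystalline=basis_profile("crystalline", q_grid),
    )


def liquid_profile_at_temperature(T: float, basis: BasisSet) -> DiffractionProfile:
    """Liquid-structure profile at temperature T.

    The evolving liquid is modelled as a convex blend of the two liquid
    references, linear in temperature between the 100 K and 280 K anchors and
    clipped outside.  Physically the blend weight tracks how much of its
    exploration the sample has spent near the high-temperature structure.
    """
    if not (LOW_T_REF <= T <= 300.0):
        raise InvalidParameterError(f"temperature {T} K outside the supported range")
    alpha = liquid_blend_weight(T)
    intensity = (1.0 - alpha) * basis.low_T.intensity + alpha * basis.high_T.intensity
    return DiffractionProfile(q=basis.q, intensity=intensity, label=f"liquid_{T:.0f}K")


def liquid_blend_weight(T) -> np.ndarray:
    """Blend weight alpha(T) of the high-temperature component, clipped to [0, 1]."""
    return np.clip(
        (np.asarray(T, dtype=float) - LOW_T_REF) / (HIGH_T_REF - LOW_T_REF), 0.0, 1.0
    )


# ---------------------------------------------------------------------------
# 2-D patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageGeometry:
    """Detector geometry mapping pixels to momentum transfer."""

    shape: tuple[int, int] = (512, 512)
    center: tuple[float, float] | None = None
    q_per_pixel: float = 0.011

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    def radii(self) -> np.ndarray:
        cy, cx = self.resolved_center()
        yy, xx = np.indices(self.shape)
        return np.hypot(yy - cy, xx - cx)


@dataclass(frozen=True)
class Pattern2D:
    """Azimuthally symmetric ring image with its q calibration."""

    image: np.ndarray
    center: tuple[float, float]
    q_per_pixel: float

    def __post_init__(self):
        cy, cx = self.center
        ny, nx = self.image.shape
        if not (0 <= cy < ny and 0 <= cx < nx):
            raise InvalidParameterError("pattern center must lie inside the image")
        if self.q_per_pixel <= 0:
            raise InvalidParameterError("q_per_pixel must be positive")


def render_pattern(
    profile: DiffractionProfile,
    geometry: ImageGeometry | None = None,
    noise: bool = False,
    seed: int | None = None,
) -> Pattern2D:
    """Render a radial profile into an azimuthally symmetric 2-D image.

    Every pixel's expected count is the profile interpolated at the pixel's
    radial q; with ``noise`` enabled each pixel is drawn from a Poisson law
    with that mean.  The profile must extend to the q of the image corners.
    """
    geometry = geometry or ImageGeometry()
    r = geometry.radii()
    q = r * geometry.q_per_pixel
    if q.max() > profile.q[-1] + 1e-12:
        raise InvalidParameterError(
            f"profile ends at q = {profile.q[-1]:.3f} but the image corners reach "
            f"q = {q.max():.3f}; extend the profile or shrink the image"
        )
    expected = profile.interpolate(q)
    if noise:
        rng = np.random.default_rng(seed)
        image = rng.poisson(expected).astype(np.int64)
    else:
        image = expected
    return Pattern2D(
        image=image, center=geometry.resolved_center(), q_per_pixel=geometry.q_per_pixel
    )


def azimuthal_average(pattern: Pattern2D, n_bins: int = 360) -> DiffractionProfile:
    """Mean count per radial bin, mapped back to a q grid.

    Pixels are assigned to bins by ``floor(r / dr)`` with
    ``dr = r_max / n_bins``; bin centers ``(i + 1/2) dr`` are converted to q
    with the pattern's calibration.  Empty bins are dropped.
    """
    if n_bins < 2:
        raise InvalidParameterError("need at least 2 radial bins")
    cy, cx = pattern.center
    yy, xx = np.indices(pattern.image.shape)
    r = np.hypot(yy - cy, xx - cx)
    dr = r.max() * (1.0 + 1e-12) / n_bins
    idx = np.floor(r / dr).astype(np.int64).ravel()
    sums = np.bincount(idx, weights=pattern.image.ravel().astype(float), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    keep = counts > 0
    q = (np.arange(len(sums)) + 0.5) * dr * pattern.q_per_pixel
    return DiffractionProfile(
        q=q[keep], intensity=sums[keep] / counts[keep], label="azimuthal_average"
    )


def write_pattern_tiff(pattern: Pattern2D, path) -> None:
    """Write a ring image as 16-bit TIFF with the calibration in the metadata."""
    import json

    import tifffile

    image = np.asarray(pattern.image)
    if image.max() >= 2**16:
        raise InvalidParameterError("counts exceed the 16-bit TIFF range")
    meta = {"center": list(pattern.center), "q_per_pixel": pattern.q_per_pixel}
    tifffile.imwrite(
        path, np.round(image).astype(np.uint16), description=json.dumps(meta)
    )


def read_pattern_tiff(path) -> Pattern2D:
    """Read a pattern written by :func:`write_pattern_tiff`."""
    import json

    import tifffile

    with tifffile.TiffFile(path) as tif:
        image = tif.asarray()
        try:
            meta = json.loads(tif.pages[0].tags["ImageDescription"].value)
            center = tuple(meta["center"])
            qpp = float(meta["q_per_pixel"])
        except (KeyError, ValueError, TypeError) as exc:
            raise InvalidParameterError(
                f"missing or malformed calibration metadata in {path}"
            ) from exc
    return Pattern2D(image=image.astype(np.int64), center=center, q_per_pixel=qpp)


def sum_replicates(profiles: list[DiffractionProfile]) -> DiffractionProfile:
    """Elementwise sum of replicate exposures sharing one q grid."""
    if not profiles:
        raise InvalidParameterError("need at least one profile")
    q0 = profiles[0].q
    for p in profiles[1:]:
        if len(p.q) != len(q0) or not np.allclose(p.q, q0):
            raise InvalidParameterError("replicates must share one q grid")
    total = np.sum([p.intensity for p in profiles], axis=0)
    return DiffractionProfile(q=q0, intensity=total, label=f"sum_of_{len(profiles)}")
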