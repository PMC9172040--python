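"""Per-pixel scattering geometry for flat and tilted detectors.

The 3D geometry is reduced to a per-pixel 2D problem: each pixel is described
by its in-detector distance ``r`` from the beam center and its azimuth ``psi``
measured counter-clockwise from the horizontal detector axis.  A detector tilt
(FIT2D convention: tilt rotation φ giving the direction of steepest tilt, and
tilt angle τ between the primary beam and the detector normal) enters through
a single per-pixel distortion angle α:

    sin α = sin τ · cos(ψ − φ)

α is the angle between the in-plane beam-center→pixel direction and the plane
normal to the beam: it vanishes along the tilt axis (ψ − φ = ±90°), equals ±τ
along the steepest-tilt direction ψ = φ, and is identically zero for an
untilted detector.  With sample-to-detector distance ``d`` (measured along the
beam to the beam center) the scattered light path and scattering angle follow
from the planar triangle sample / beam-center / pixel:

    l = sqrt(d² + r² + 2 d r sin α),      cos 2θ = (d + r sin α) / l

and the scattering-vector magnitude is q = (4π/λ) sin θ, reported in nm⁻¹.
Positive τ tips the detector region at azimuth ψ = φ downstream, away from
the sample.  All angles are stored in radians internally; the calibration
carries degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import GeometrySpec

__all__ = [
    "PixelPolarMap",
    "DistortionMap",
    "QMap",
    "pixel_polar_coordinates",
    "distortion_angle",
    "light_path",
    "scattering_vector",
    "build_qmap",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PixelPolarMap:
    """Per-pixel polar coordinates: ``r`` in mm, ``psi`` in radians [0, 2π)."""

    r: np.ndarray
    psi: np.ndarray


@dataclass(frozen=True)
class DistortionMap:
    """Per-pixel tilt distortion angle α, radians."""

    alpha: np.ndarray


@dataclass(frozen=True)
class QMap:
    """Per-pixel light path ``l`` (mm), scattering angle ``two_theta`` (rad)
    and scattering-vector magnitude ``q`` (nm⁻¹)."""

    l: np.ndarray
    two_theta: np.ndarray
    q: np.ndarray


def _pixel_grids(geom: GeometrySpec, rows, cols):
    if rows is None or cols is None:
        nv, nh = geom.image_size
        rows, cols = np.meshgrid(np.arange(nv, dtype=float), np.arange(nh, dtype=float), indexing="ij")
    return np.asarray(rows, dtype=float), np.asarray(cols, dtype=float)


def pixel_polar_coordinates(geom: GeometrySpec, rows=None, cols=None) -> PixelPolarMap:
    """Distance from the beam center (mm) and azimuth for each pixel.

    ``rows``/``cols`` default to the full pixel-center grid of the calibrated
    image; fractional coordinates (subpixel positions) are allowed.  The
    azimuth is measured from the rightward horizontal axis, counter-clockwise
    as seen looking downstream, with the vertical axis pointing up (i.e.
    toward smaller row indices).
    """
    rows, cols = _pixel_grids(geom, rows, cols)
    pv, ph = geom.pixel_size  # µm
    bcv, bch = geom.beamcenter
    dx = (cols - bch) * ph * 1e-3  # mm, rightward
    dy = -(rows - bcv) * pv * 1e-3  # mm, upward
    r = np.hypot(dx, dy)
    psi = np.mod(np.arctan2(dy, dx), _TWO_PI)
    return PixelPolarMap(r=r, psi=psi)


def distortion_angle(polar: PixelPolarMap, geom: GeometrySpec) -> DistortionMap:
    """Tilt distortion angle α = arcsin(sin τ · cos(ψ − φ)) per pixel."""
    phi = math.radians(geom.tilt_rotation)
    tau = math.radians(geom.tilt_angle)
    if tau == 0.0:
        return DistortionMap(alpha=np.zeros_like(polar.psi))
    alpha = np.arcsin(math.sin(tau) * np.cos(polar.psi - phi))
    return DistortionMap(alpha=alpha)


def light_path(polar: PixelPolarMap, dist: DistortionMap, geom: GeometrySpec) -> np.ndarray:
    """Scattered light path ``l = sqrt(d² + r² + 2 d r sin α)``, mm."""
    d = geom.detector_distance
    r = polar.r
    return np.sqrt(d * d + r * r + 2.0 * d * r * np.sin(dist.alpha))


def scattering_vector(
    polar: PixelPolarMap,
    dist: DistortionMap,
    l: np.ndarray,
    geom: GeometrySpec,
    wavelength: float,
) -> QMap:
    """Scattering angle 2θ and magnitude q = (4π/λ) sin θ.

    ``wavelength`` is in Å; q comes out in nm⁻¹ (a factor 10 above Å⁻¹).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    d = geom.detector_distance
    # cos(2θ) = projection of the sample->pixel ray on the beam axis
    cos_2t = np.clip((d + polar.r * np.sin(dist.alpha)) / l, -1.0, 1.0)
    two_theta = np.arccos(cos_2t)
    q = (4.0 * math.pi / wavelength) * np.sin(0.5 * two_theta) * 10.0
    return QMap(l=l, two_theta=two_theta, q=q)


_QMAP_CACHE: dict[tuple, QMap] = {}


def build_qmap(geom: GeometrySpec, wavelength: float, rows=None, cols=None) -> QMap:
    """Compose the polar map, distortion angle, light path and q magnitude.

    Full-grid maps are cached per (geometry, wavelength) and reused across
    frames sharing a calibration; passing explicit coordinates bypasses the
    cache (used for subpixel evaluation during oversampled rebinning).
    """
    full_grid = rows is None and cols is None
    key = (geom, float(wavelength))
    if full_grid and key in _QMAP_CACHE:
        return _QMAP_CACHE[key]
    polar = pixel_polar_coordinates(geom, rows, cols)
    dist = distortion_angle(polar, geom)
    l = light_path(polar, dist, geom)
    qmap = scattering_vector(polar, dist, l, geom, wavelength)
    if full_grid:
        _QMAP_CACHE[key] = qmap
    return qmap
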