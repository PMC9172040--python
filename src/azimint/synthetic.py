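"""Synthetic detector frames, masks and brute-force oracles.

Everything the test suite and the examples need is generated here with known
ground truth: flat fields, rings, isotropic frames following an analytic
radial profile I₀(q) (optionally with Poisson counting noise), bit-exact
``.msk`` masks, and two independent reference implementations — a per-pixel
integration loop and a 3D ray-construction of the tilted-detector q map —
used to validate the sparse-matrix and closed-form production paths.

The default synthetic geometry mimics a small photon-counting detector:
256×256 pixels of 172 µm at 1000 mm distance, λ = 1.54 Å, beam center in the
middle of the frame.  This keeps tests sub-second while staying realistic in
q range (≈ 0–1.8 nm⁻¹ over the half-diagonal).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Callable

import numpy as np
import tifffile

from .calibration import GeometrySpec
from .geometry import QMap, build_qmap, pixel_polar_coordinates
from .integrator import IntegratedCurve, RadialBinning
from .masks import write_fit2d_mask

__all__ = [
    "default_geometry",
    "FramePrescription",
    "make_flat_frame",
    "make_isotropic_frame",
    "make_ring_frame",
    "make_mask",
    "sphere_form_factor",
    "write_frame",
    "oracle_integrate",
    "oracle_q_3d",
]


def default_geometry(
    image_size: tuple[int, int] = (256, 256),
    beamcenter: tuple[float, float] | None = None,
    tilt_rotation: float = 0.0,
    tilt_angle: float = 0.0,
) -> GeometrySpec:
    """The package's standard small synthetic geometry (see module docstring)."""
    if beamcenter is None:
        beamcenter = (image_size[0] / 2.0, image_size[1] / 2.0)
    return GeometrySpec(
        beamcenter=beamcenter,
        detector_distance=1000.0,
        image_size=image_size,
        pixel_size=(172.0, 172.0),
        tilt_rotation=tilt_rotation,
        tilt_angle=tilt_angle,
    )


DEFAULT_WAVELENGTH = 1.54  # Å, Cu Kα — typical laboratory/synchrotron choice


@dataclass(frozen=True)
class FramePrescription:
    """Recipe for an isotropic synthetic frame: profile I₀(q), geometry,
    wavelength and (optionally seeded Poisson) noise."""

    profile: Callable[[np.ndarray], np.ndarray]
    geometry: GeometrySpec
    wavelength: float = DEFAULT_WAVELENGTH
    noise: str = "none"  # "none" | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


def make_flat_frame(shape: tuple[int, int], value: float) -> np.ndarray:
    """Constant frame."""
    if value < 0:
        raise ValueError("value must be non-negative")
    return np.full(shape, float(value))


def make_isotropic_frame(prescription: FramePrescription) -> np.ndarray:
    """Frame whose pixel value is I₀(q(pixel)), optionally Poisson-sampled."""
    qmap = build_qmap(prescription.geometry, prescription.wavelength)
    vals = np.asarray(prescription.profile(qmap.q), dtype=float)
    if np.any(vals < 0):
        raise ValueError("the radial profile must be non-negative")
    if prescription.noise == "poisson":
        rng = np.random.default_rng(prescription.seed)
        vals = rng.poisson(vals).astype(float)
    return vals


def make_ring_frame(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius_px: float,
    width_px: float,
    value: float,
) -> np.ndarray:
    """Annulus of constant value (pixel-radius units), zero elsewhere."""
    rows, cols = np.meshgrid(
        np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float), indexing="ij"
    )
    r = np.hypot(rows - center[0], cols - center[1])
    frame = np.zeros(shape)
    if width_px > 0:
        frame[np.abs(r - radius_px) <= width_px / 2.0] = value
    return frame


def make_mask(shape: tuple[int, int], masked_pixels, path=None) -> np.ndarray:
    """Boolean mask with the given (row, col) pixels excluded; optionally
    written as a bit-exact ``.msk`` file."""
    mask = np.zeros(shape, dtype=bool)
    for rc in masked_pixels:
        mask[tuple(rc)] = True
    if path is not None:
        write_fit2d_mask(mask, path)
    return mask


def sphere_form_factor(q: np.ndarray, radius_nm: float = 5.0, scale: float = 1.0) -> np.ndarray:
    """Normalized sphere form factor P(q) = [3(sin x − x cos x)/x³]², x = qR.

    P(0) = 1; the q → 0 limit is handled by series expansion so frames are
    smooth through the beam center.
    """
    x = np.asarray(q, dtype=float) * radius_nm
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = (3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3) ** 2
    out[small] = 1.0 - x[small] ** 2 / 5.0  # series of P(q) near 0
    return scale * out


def write_frame(frame: np.ndarray, path, timestamp: str | None = None) -> None:
    """Write a frame as a single-page int32 TIFF (Pilatus-style counts).

    ``timestamp`` (``YYYY:MM:DD HH:MM:SS``) is stored in the TIFF DateTime
    tag, emulating the acquisition-time header of photon-counting detectors.
    """
    extratags = None
    if timestamp is not None:
        extratags = [(306, "s", 0, timestamp, False)]
    tifffile.imwrite(path, np.asarray(frame).astype(np.int32), extratags=extratags)


def oracle_integrate(
    frame: np.ndarray,
    qmap: QMap,
    binning: RadialBinning,
    mask: np.ndarray,
) -> IntegratedCurve:
    """Brute-force reference integration: an explicit per-pixel loop.

    Each unmasked, non-negative pixel is assigned by its center q to the
    containing bin (found by bisection over the edge list, clipped to the
    binning span) and plain averages are taken.  No sparse algebra — this is
    the independent oracle for the k = 1 matrix path.
    """
    edges = list(binning.q_edges)
    nb = binning.n_bins
    sums = [0.0] * nb
    counts = [0] * nb
    nv, nh = frame.shape
    for i in range(nv):
        for j in range(nh):
            if mask[i, j]:
                continue
            v = float(frame[i, j])
            if not np.isfinite(v) or v < 0:
                continue
            q = float(qmap.q[i, j])
            if q < edges[0] or q > edges[-1]:
                continue
            b = bisect_right(edges, q) - 1
            if b >= nb:
                b = nb - 1
            sums[b] += v
            counts[b] += 1
    q_out, I_out, E_out, A_out = [], [], [], []
    for b in range(nb):
        if counts[b] == 0:
            continue
        mean = sums[b] / counts[b]
        q_out.append(binning.q_centers[b])
        I_out.append(mean)
        E_out.append(0.0 if mean == 0 else (mean / counts[b]) ** 0.5)
        A_out.append(float(counts[b]))
    return IntegratedCurve(
        q=np.array(q_out), I=np.array(I_out), E=np.array(E_out), A=np.array(A_out)
    )


def oracle_q_3d(geom: GeometrySpec, wavelength: float, rows=None, cols=None) -> np.ndarray:
    """Independent tilted-detector q map by explicit 3D ray construction.

    Builds the tilted detector plane in 3D (rotating the in-plane
    beam-center→pixel vectors about the tilt axis with a scipy rotation),
    places each pixel, and takes the angle between the incident beam and the
    sample→pixel ray.  Shares only the geometric convention with the
    closed-form production path, not its algebra.
    """
    import math

    from scipy.spatial.transform import Rotation

    polar = pixel_polar_coordinates(geom, rows, cols)
    # in-plane displacement in the untilted detector frame (x right, y up)
    vx = polar.r * np.cos(polar.psi)
    vy = polar.r * np.sin(polar.psi)
    v0 = np.stack([vx.ravel(), vy.ravel(), np.zeros(vx.size)], axis=1)
    phi = math.radians(geom.tilt_rotation)
    tau = math.radians(geom.tilt_angle)
    axis = np.array([-math.sin(phi), math.cos(phi), 0.0])  # tilt axis at ψ = φ + 90°
    v = Rotation.from_rotvec(-tau * axis).apply(v0)
    p = v + np.array([0.0, 0.0, geom.detector_distance])
    norm = np.linalg.norm(p, axis=1)
    cos2t = np.clip(p[:, 2] / norm, -1.0, 1.0)
    theta = 0.5 * np.arccos(cos2t)
    q = (4.0 * math.pi / wavelength) * np.sin(theta) * 10.0
    return q.reshape(vx.shape)
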