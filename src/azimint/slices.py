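"""GISAXS line cuts in detector coordinates.

For grazing-incidence experiments the package extracts horizontal and
vertical line slices through the detector image: a band of ``2·margin + 1``
rows (or columns) centred on a fixed pixel position is averaged
perpendicular to the slice direction.  The slice axis is expressed as the
detector-plane scattering-vector component q_H (horizontal, x slices) or q_V
(vertical, y slices) using the zero-tilt mapping
``q = ±(4π/λ)·sin(atan(Δ/d)/2)``; no Ewald-sphere distortion correction is
applied and the beam incidence angle is neglected, so the axis is exact only
at small angles — a deliberate quick-look limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import GeometrySpec, SliceSpec

__all__ = ["SliceCurve", "slice_q_axis", "extract_slice", "write_slice_chi", "read_slice_chi"]


@dataclass(frozen=True)
class SliceCurve:
    """One extracted line cut: q component, mean intensity, Poisson error."""

    q_axis: np.ndarray
    I: np.ndarray
    E: np.ndarray
    axis_label: str
    thickness_pixels: int
    direction: str = "x"
    plane: str = "InPlane"
    position: int = 0
    margin: int = 0

    def __post_init__(self) -> None:
        if not (len(self.q_axis) == len(self.I) == len(self.E)):
            raise ValueError("q_axis, I and E must have equal length")


def _q_component(delta_mm: np.ndarray, d_mm: float, wavelength: float) -> np.ndarray:
    # zero-tilt detector-plane mapping, consistent with the radial q definition
    # along the horizontal/vertical axes; sign carries the side of the beam
    two_theta = np.arctan(np.abs(delta_mm) / d_mm)
    return np.sign(delta_mm) * (4.0 * math.pi / wavelength) * np.sin(0.5 * two_theta) * 10.0


def slice_q_axis(spec: SliceSpec, geom: GeometrySpec, wavelength: float) -> np.ndarray:
    """q_H (x slice) or q_V (y slice) for every pixel index along the slice.

    Antisymmetric about the beam center; positive to the right (x) and upward
    (y).  Detector tilt is ignored, matching the slice semantics above.
    """
    nv, nh = geom.image_size
    pv, ph = geom.pixel_size
    if spec.direction == "x":
        delta = (np.arange(nh, dtype=float) - geom.beamcenter[1]) * ph * 1e-3
    else:
        delta = -(np.arange(nv, dtype=float) - geom.beamcenter[0]) * pv * 1e-3
    return _q_component(delta, geom.detector_distance, wavelength)


def extract_slice(
    frame: np.ndarray,
    spec: SliceSpec,
    mask: np.ndarray,
    geom: GeometrySpec,
    wavelength: float,
) -> SliceCurve:
    """Average the slice band and attach the q axis and Poisson errors.

    For an x slice, rows ``position ± margin`` are averaged per column; a y
    slice transposes the roles.  Masked pixels and negative sentinel counts
    never contribute; points whose band is fully excluded are omitted rather
    than emitted as zero.
    """
    frame = np.asarray(frame)
    nv, nh = geom.image_size
    if frame.shape != (nv, nh):
        raise ValueError(f"frame shape {frame.shape} does not match image size {(nv, nh)}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise ValueError("mask shape does not match frame shape")
    lo, hi = spec.position - spec.margin, spec.position + spec.margin
    bound = nv if spec.direction == "x" else nh
    if lo < 0 or hi >= bound:
        raise ValueError("slice band (position +/- margin) exceeds the image bounds")

    if spec.direction == "x":
        band = frame[lo : hi + 1, :].astype(float)
        band_mask = mask[lo : hi + 1, :]
    else:
        band = frame[:, lo : hi + 1].astype(float).T
        band_mask = mask[:, lo : hi + 1].T

    valid = (~band_mask) & np.isfinite(band) & (band >= 0)
    A = valid.sum(axis=0).astype(float)
    total = np.where(valid, band, 0.0).sum(axis=0)
    q_axis = slice_q_axis(spec, geom, wavelength)
    emit = A > 0
    I = total[emit] / A[emit]
    with np.errstate(invalid="ignore"):
        E = np.where(I == 0, 0.0, np.sqrt(I / A[emit]))
    label = "q_H" if spec.direction == "x" else "q_V"
    return SliceCurve(
        q_axis=q_axis[emit],
        I=I,
        E=E,
        axis_label=label,
        thickness_pixels=2 * spec.margin + 1,
        direction=spec.direction,
        plane=spec.plane,
        position=spec.position,
        margin=spec.margin,
    )


def write_slice_chi(curve: SliceCurve, path) -> None:
    """Write a slice as a three-column text file with slice metadata header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# slice direction: {curve.direction} plane: {curve.plane} "
            f"position: {curve.position} margin: {curve.margin}\n"
        )
        fh.write(f"# columns: {curve.axis_label}[nm^-1]  I[counts/pixel]  E\n")
        fh.write(f"# points: {len(curve.q_axis)}\n")
        for q, i, e in zip(curve.q_axis, curve.I, curve.E):
            fh.write(f"{q:.12e} {i:.12e} {e:.12e}\n")


def read_slice_chi(path) -> SliceCurve:
    """Read back a slice file written by :func:`write_slice_chi`."""
    qs, Is, Es = [], [], []
    meta = {"direction": "x", "plane": "InPlane", "position": 0, "margin": 0}
    label = "q_H"
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# slice"):
                toks = line.split()
                meta["direction"] = toks[3]
                meta["plane"] = toks[5]
                meta["position"] = int(toks[7])
                meta["margin"] = int(toks[9])
                continue
            if line.startswith("# columns:"):
                label = line.split()[2].split("[")[0]
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            qs.append(float(parts[0]))
            Is.append(float(parts[1]))
            Es.append(float(parts[2]))
    return SliceCurve(
        q_axis=np.array(qs),
        I=np.array(Is),
        E=np.array(Es),
        axis_label=label,
        thickness_pixels=2 * meta["margin"] + 1,
        **meta,
    )
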