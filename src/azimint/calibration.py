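"""Experiment calibration: geometry, masks, slices and integration parameters.

The calibration is a JSON document describing everything needed to reduce a
detector frame: beam center, sample-to-detector distance, pixel layout,
detector tilt, the list of integration masks (each with its own oversampling
factor, radial step width and classifier q-window), optional GISAXS slices,
the X-ray wavelength, watched directories and the worker count.

Units follow beamline convention: lengths in mm (detector distance), pixel
sizes in µm, wavelength in Å, q boundaries in nm⁻¹, angles in degrees.
Coordinates throughout the package are (vertical, horizontal) = (row, column),
0-based, origin at the top-left stored pixel; the beam center may be
fractional and lives in the same pixel-center frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any

__all__ = [
    "CalibrationError",
    "GeometrySpec",
    "MaskSpec",
    "SliceSpec",
    "CalibrationSpec",
    "parse_calibration",
    "write_calibration",
    "read_calibration",
    "save_calibration",
]


class CalibrationError(ValueError):
    """Raised when a calibration document is missing keys or fails validation."""


@dataclass(frozen=True)
class GeometrySpec:
    """Detector geometry.

    Parameters
    ----------
    beamcenter : (float, float)
        Beam-center position ``(vertical, horizontal)`` in pixel units;
        fractional values are allowed.
    detector_distance : float
        Sample-to-detector distance along the beam, mm.
    image_size : (int, int)
        Sensor dimensions ``(vertical, horizontal)`` in pixels.
    pixel_size : (float, float)
        Pixel size ``(vertical, horizontal)``, µm.
    tilt_rotation : float
        Tilt-rotation angle φ (direction of steepest tilt), degrees.
    tilt_angle : float
        Tilt angle τ between the primary beam and the detector normal, degrees.
    """

    beamcenter: tuple[float, float]
    detector_distance: float
    image_size: tuple[int, int]
    pixel_size: tuple[float, float]
    tilt_rotation: float = 0.0
    tilt_angle: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beamcenter", tuple(float(x) for x in self.beamcenter))
        object.__setattr__(self, "image_size", tuple(int(x) for x in self.image_size))
        object.__setattr__(self, "pixel_size", tuple(float(x) for x in self.pixel_size))
        if len(self.beamcenter) != 2 or len(self.image_size) != 2 or len(self.pixel_size) != 2:
            raise CalibrationError("beamcenter, image size and pixel size must each have two components")
        if any(n <= 0 for n in self.image_size):
            raise CalibrationError("image size components must be positive")
        if any(p <= 0 for p in self.pixel_size):
            raise CalibrationError("pixel size components must be positive")
        if self.detector_distance <= 0:
            raise CalibrationError("detector distance must be positive")
        if abs(self.tilt_angle) >= 90.0:
            raise CalibrationError("tilt angle must satisfy |tau| < 90 degrees")


@dataclass(frozen=True)
class MaskSpec:
    """One integration configuration: mask file plus binning parameters.

    ``q_start``/``q_stop`` (nm⁻¹) bound the window over which the image
    classifiers (integral parameters) are computed.
    """

    path_to_file: str
    oversampling: int = 1
    pix_per_rad_element: float = 1.0
    q_start: float = 0.0
    q_stop: float = 10.0

    def __post_init__(self) -> None:
        if int(self.oversampling) != self.oversampling or self.oversampling < 1:
            raise CalibrationError("oversampling must be an integer >= 1")
        object.__setattr__(self, "oversampling", int(self.oversampling))
        if self.pix_per_rad_element <= 0:
            raise CalibrationError("pix. p. rad. element must be positive")
        if not self.q_start < self.q_stop:
            raise CalibrationError("q-start must be smaller than q-stop")


@dataclass(frozen=True)
class SliceSpec:
    """A GISAXS line cut in detector coordinates.

    ``direction`` is the axis the cut runs along (``"x"`` = along columns,
    ``"y"`` = along rows); ``position`` is the 0-based pixel index of the
    perpendicular coordinate (row index for an x slice, column index for a
    y slice); ``margin`` pixels on either side are averaged, so the band is
    ``2*margin + 1`` pixels thick.  ``plane`` records the orientation relative
    to the scattering surface (``"InPlane"`` or ``"Vertical"``) and is
    bookkeeping only.
    """

    direction: str
    plane: str
    position: int
    margin: int = 0
    mask_reference: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("x", "y"):
            raise CalibrationError("slice direction must be 'x' or 'y'")
        if self.plane not in ("InPlane", "Vertical"):
            raise CalibrationError("slice plane must be 'InPlane' or 'Vertical'")
        if self.margin < 0:
            raise CalibrationError("slice margin must be >= 0")
        if self.position < 0:
            raise CalibrationError("slice position must be >= 0")


@dataclass(frozen=True)
class CalibrationSpec:
    """Full experiment description driving the reduction pipeline."""

    geometry: GeometrySpec
    masks: tuple[MaskSpec, ...]
    wavelength: float
    slices: tuple[SliceSpec, ...] = ()
    directory: tuple[str, ...] = ()
    threads: int = 1
    extra: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "masks", tuple(self.masks))
        object.__setattr__(self, "slices", tuple(self.slices))
        object.__setattr__(self, "directory", tuple(self.directory))
        if self.wavelength <= 0:
            raise CalibrationError("wavelength must be positive")
        if self.threads < 1:
            raise CalibrationError("threads must be >= 1")
        if not self.masks:
            raise CalibrationError("at least one mask entry is required")
        nmask = len(self.masks)
        for sl in self.slices:
            if not 0 <= sl.mask_reference < nmask:
                raise CalibrationError(
                    f"slice mask reference {sl.mask_reference} out of range (have {nmask} masks)"
                )
            v, h = self.geometry.image_size
            bound = v if sl.direction == "x" else h
            if not 0 <= sl.position < bound:
                raise CalibrationError(f"slice position {sl.position} outside image bounds")
            if sl.position - sl.margin < 0 or sl.position + sl.margin >= bound:
                raise CalibrationError("slice band (position +/- margin) exceeds image bounds")

    def with_threads(self, threads: int) -> "CalibrationSpec":
        return replace(self, threads=threads)


# JSON keys of the on-disk calibration document.
_GEOM_KEYS = ("beamcenter", "detector distance", "image size", "pixel size")
_MASK_KEYS = ("path to file", "oversampling", "pix. p. rad. element", "q-start", "q-stop")
_SLICE_KEYS = ("direction", "plane", "position", "margin", "mask reference")
_TOP_KEYS = ("geometry", "masks", "wavelength", "directory", "threads")


def _require(obj: dict, key: str, where: str) -> Any:
    if key not in obj:
        raise CalibrationError(f"calibration is missing mandatory key '{key}' (in {where})")
    return obj[key]


def parse_calibration(text: str | dict) -> CalibrationSpec:
    """Parse and validate a calibration JSON document.

    Accepts the JSON text or an already-decoded dictionary.  Raises
    :class:`CalibrationError` naming the offending key when a mandatory entry
    is missing or fails validation.  Unknown extra keys are preserved on the
    returned spec and round-trip through :func:`write_calibration`.
    """
    if isinstance(text, str):
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CalibrationError(f"calibration is not well-formed JSON: {exc}") from exc
    else:
        doc = dict(text)
    if not isinstance(doc, dict):
        raise CalibrationError("calibration document must be a JSON object")

    gdoc = _require(doc, "geometry", "top level")
    for key in _GEOM_KEYS:
        _require(gdoc, key, "geometry")
    tilt = gdoc.get("tilt", {})
    try:
        geometry = GeometrySpec(
            beamcenter=tuple(gdoc["beamcenter"]),
            detector_distance=float(gdoc["detector distance"]),
            image_size=tuple(gdoc["image size"]),
            pixel_size=tuple(gdoc["pixel size"]),
            tilt_rotation=float(tilt.get("tilt rotation", 0.0)),
            tilt_angle=float(tilt.get("tilt angle", 0.0)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, CalibrationError):
            raise
        raise CalibrationError(f"invalid geometry value: {exc}") from exc

    mdocs = _require(doc, "masks", "top level")
    if not isinstance(mdocs, list) or not mdocs:
        raise CalibrationError("'masks' must be a non-empty array")
    masks = []
    for i, md in enumerate(mdocs):
        _require(md, "path to file", f"masks[{i}]")
        try:
            masks.append(
                MaskSpec(
                    path_to_file=str(md["path to file"]),
                    oversampling=md.get("oversampling", 1),
                    pix_per_rad_element=float(md.get("pix. p. rad. element", 1.0)),
                    q_start=float(md.get("q-start", 0.0)),
                    q_stop=float(md.get("q-stop", 10.0)),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, CalibrationError):
                raise
            raise CalibrationError(f"invalid value in masks[{i}]: {exc}") from exc

    slices = []
    for i, sd in enumerate(doc.get("slices", []) or []):
        for key in ("direction", "plane", "position"):
            _require(sd, key, f"slices[{i}]")
        try:
            slices.append(
                SliceSpec(
                    direction=str(sd["direction"]),
                    plane=str(sd["plane"]),
                    position=int(sd["position"]),
                    margin=int(sd.get("margin", 0)),
                    mask_reference=int(sd.get("mask reference", 0)),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, CalibrationError):
                raise
            raise CalibrationError(f"invalid value in slices[{i}]: {exc}") from exc

    wavelength = _require(doc, "wavelength", "top level")
    try:
        wavelength = float(wavelength)
    except (TypeError, ValueError) as exc:
        raise CalibrationError("'wavelength' must be a number") from exc

    directory = doc.get("directory", [])
    if isinstance(directory, str):
        directory = [directory]
    threads = doc.get("threads", 1)
    if int(threads) != threads:
        raise CalibrationError("'threads' must be an integer")

    extra = {k: v for k, v in doc.items() if k not in _TOP_KEYS + ("slices",)}
    return CalibrationSpec(
        geometry=geometry,
        masks=tuple(masks),
        slices=tuple(slices),
        wavelength=wavelength,
        directory=tuple(str(d) for d in directory),
        threads=int(threads),
        extra=extra,
    )


def write_calibration(spec: CalibrationSpec) -> str:
    """Serialize a calibration to its JSON document form.

    ``parse_calibration(write_calibration(spec)) == spec`` for every valid spec.
    """
    g = spec.geometry
    doc: dict[str, Any] = dict(spec.extra)
    doc["geometry"] = {
        "beamcenter": list(g.beamcenter),
        "detector distance": g.detector_distance,
        "image size": list(g.image_size),
        "pixel size": list(g.pixel_size),
        "tilt": {"tilt rotation": g.tilt_rotation, "tilt angle": g.tilt_angle},
    }
    doc["masks"] = [
        {
            "path to file": m.path_to_file,
            "oversampling": m.oversampling,
            "pix. p. rad. element": m.pix_per_rad_element,
            "q-start": m.q_start,
            "q-stop": m.q_stop,
        }
        for m in spec.masks
    ]
    if spec.slices:
        doc["slices"] = [
            {
                "direction": s.direction,
                "plane": s.plane,
                "position": s.position,
                "margin": s.margin,
                "mask reference": s.mask_reference,
            }
            for s in spec.slices
        ]
    doc["wavelength"] = spec.wavelength
    doc["directory"] = list(spec.directory)
    doc["threads"] = spec.threads
    return json.dumps(doc, indent=2)


def read_calibration(path) -> CalibrationSpec:
    """Load a calibration JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_calibration(fh.read())


def save_calibration(spec: CalibrationSpec, path) -> None:
    """Write a calibration JSON file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_calibration(spec))
        fh.write("\n")
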