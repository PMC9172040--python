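"""Per-image scalar classifiers and their time history.

Each reduced curve is condensed to three quick-look integral parameters over
the configured window [q_start, q_stop]:

* integral intensity   ∫ I(q) dq
* invariant            ∫ q² I(q) dq  (the Porod invariant over the window,
  proportional to the total scattering contrast volume)
* correlation length   l_c = π · ∫ q I dq / ∫ q² I dq  (nm)

Integrals are trapezoidal over the curve points inside the window; no
extrapolation to q → 0 or q → ∞ is attempted, so the values are window-bound
monitors of kinetics rather than absolute structural parameters.  Degenerate
cases (fewer than two in-window points, zero invariant) yield NaN, flagged by
``ClassifierRecord.valid``.
"""

from __future__ import annotations

import math
import re
from bisect import insort
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from .calibration import MaskSpec
from .integrator import IntegratedCurve

__all__ = [
    "integral_intensity",
    "porod_invariant",
    "correlation_length",
    "compute_classifiers",
    "ClassifierRecord",
    "ClassifierHistory",
    "dataset_name",
    "acquisition_time",
]


def _window(curve: IntegratedCurve, q1: float, q2: float):
    if not q1 < q2:
        raise ValueError("q1 must be smaller than q2")
    sel = (curve.q >= q1) & (curve.q <= q2)
    return curve.q[sel], curve.I[sel]


def integral_intensity(curve: IntegratedCurve, q1: float, q2: float) -> float:
    """Trapezoidal ∫ I dq over curve points inside [q1, q2]; NaN if < 2 points."""
    q, I = _window(curve, q1, q2)
    if len(q) < 2:
        return math.nan
    return float(np.trapezoid(I, q))


def porod_invariant(curve: IntegratedCurve, q1: float, q2: float) -> float:
    """Trapezoidal ∫ q² I dq over [q1, q2]; NaN if < 2 points."""
    q, I = _window(curve, q1, q2)
    if len(q) < 2:
        return math.nan
    return float(np.trapezoid(q * q * I, q))


def correlation_length(curve: IntegratedCurve, q1: float, q2: float) -> float:
    """l_c = π · ∫ q I dq / ∫ q² I dq over [q1, q2], nm; NaN when the
    invariant vanishes (featureless or empty window)."""
    q, I = _window(curve, q1, q2)
    if len(q) < 2:
        return math.nan
    inv = float(np.trapezoid(q * q * I, q))
    if inv <= 0:
        return math.nan
    return float(math.pi * np.trapezoid(q * I, q) / inv)


@dataclass(frozen=True, order=True)
class ClassifierRecord:
    """Scalar summaries of one image, keyed by acquisition time."""

    acquired_at: datetime
    source: str = field(compare=False)
    integral_intensity: float = field(compare=False)
    invariant: float = field(compare=False)
    correlation_length: float = field(compare=False)

    @property
    def valid(self) -> bool:
        return all(
            math.isfinite(v)
            for v in (self.integral_intensity, self.invariant, self.correlation_length)
        )


def compute_classifiers(
    curve: IntegratedCurve,
    spec: MaskSpec,
    source: str,
    acquired_at: datetime,
) -> ClassifierRecord:
    """All three classifiers on the spec's [q_start, q_stop] window."""
    return ClassifierRecord(
        acquired_at=acquired_at,
        source=str(source),
        integral_intensity=integral_intensity(curve, spec.q_start, spec.q_stop),
        invariant=porod_invariant(curve, spec.q_start, spec.q_stop),
        correlation_length=correlation_length(curve, spec.q_start, spec.q_stop),
    )


_FRAME_NUMBER = re.compile(r"[_-]?\d+$")


def dataset_name(source: str) -> str:
    """Data-set key of an image: filename prefix before the trailing frame
    number (serial-acquisition naming, e.g. ``lipid_scan_00042.tif`` →
    ``lipid_scan``)."""
    stem = Path(source).stem
    return _FRAME_NUMBER.sub("", stem)


def acquisition_time(path) -> datetime:
    """Acquisition timestamp of an image: the TIFF DateTime tag when present
    (photon-counting detectors embed it), else the file modification time."""
    try:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            tag = tf.pages[0].tags.get("DateTime")
            if tag is not None:
                return datetime.strptime(str(tag.value), "%Y:%m:%d %H:%M:%S")
    except Exception:
        pass
    return datetime.fromtimestamp(Path(path).stat().st_mtime)


class ClassifierHistory:
    """Time-ordered, queryable collection of classifier records.

    Insertion keeps records sorted by acquisition time regardless of arrival
    order, so online (out-of-order worker completion) and offline runs build
    identical histories.
    """

    def __init__(self, records=()) -> None:
        self._records: list[ClassifierRecord] = []
        for rec in records:
            self.insert(rec)

    def insert(self, record: ClassifierRecord) -> None:
        insort(self._records, record)

    @property
    def records(self) -> tuple[ClassifierRecord, ...]:
        return tuple(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def query(self, dataset: str | None = None) -> "ClassifierHistory":
        """Non-destructive filter by data set; ``None`` returns everything."""
        if dataset is None:
            return ClassifierHistory(self._records)
        return ClassifierHistory(
            r for r in self._records if dataset_name(r.source) == dataset
        )

    def datasets(self) -> tuple[str, ...]:
        seen = dict.fromkeys(dataset_name(r.source) for r in self._records)
        return tuple(seen)

    def export_tsv(self, path) -> None:
        """One row per record: source, ISO-8601 time, the three classifiers."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\tacquired_at\tintegral_intensity\tinvariant\tcorrelation_length\n")
            for r in self._records:
                fh.write(
                    f"{r.source}\t{r.acquired_at.isoformat()}\t"
                    f"{r.integral_intensity!r}\t{r.invariant!r}\t{r.correlation_length!r}\n"
                )
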