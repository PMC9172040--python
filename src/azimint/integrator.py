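"""Azimuthal integration via a sparse pixel→bin weighting matrix.

The reduction is a matrix–vector product: the flattened image ``p`` (length
n_pixels) is multiplied by a sparse weighting matrix ``C`` (n_bins × n_pixels)
whose entry ``C[j, i]`` is the fraction of pixel ``i`` assigned to radial
element ``j``.  The per-bin effective area is ``A = C · 1`` and the
azimuthally averaged intensity is ``I = (C · p) / A``.  Counting statistics of
photon detection are Poissonian, so the error of the bin mean is
``E = sqrt(I / A)``.

Anti-aliasing: each pixel is subdivided into ``k × k`` equal subpixels and
each subpixel center deposits weight ``1/k²`` into the bin containing its q
value.  Pixels straddling a bin border are thus shared fractionally between
neighbouring bins, while the column sum for every unmasked in-range pixel
stays exactly 1 — intensity is conserved by construction for every ``k``.

Masked pixels appear as structurally empty columns of ``C``; per-frame
negative sentinel counts (module-gap markers of photon-counting detectors)
are additionally excluded frame by frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .calibration import GeometrySpec
from .geometry import QMap, build_qmap

__all__ = [
    "RadialBinning",
    "WeightMatrix",
    "IntegratedCurve",
    "build_binning",
    "build_weight_matrix",
    "bin_areas",
    "integrate_frame",
    "poisson_errors",
    "write_chi",
    "read_chi",
]


@dataclass(frozen=True)
class RadialBinning:
    """Uniform q binning: ``n_bins`` bins spanning ``[q_edges[0], q_edges[-1]]``."""

    n_bins: int
    q_centers: np.ndarray
    q_edges: np.ndarray

    def __post_init__(self) -> None:
        if len(self.q_edges) != self.n_bins + 1:
            raise ValueError("q_edges must have n_bins + 1 entries")
        if np.any(np.diff(self.q_edges) <= 0):
            raise ValueError("q_edges must be strictly increasing")


@dataclass(frozen=True)
class WeightMatrix:
    """Sparse weighting matrix ``C`` (n_bins × n_pixels) plus area vector ``A``."""

    C: sp.csr_matrix
    A: np.ndarray
    image_shape: tuple[int, int]

    def column_sums(self) -> np.ndarray:
        """Per-pixel total weight (1 for unmasked in-range pixels, else < 1)."""
        return np.asarray(self.C.sum(axis=0)).ravel()


@dataclass(frozen=True)
class IntegratedCurve:
    """A reduced 1D curve: q (nm⁻¹), mean intensity per pixel, error of the mean.

    ``A`` carries the per-bin effective integration area actually used for the
    frame (static mask plus per-frame sentinel exclusions); it is auxiliary
    and not part of equality or the .chi file contract.
    """

    q: np.ndarray
    I: np.ndarray
    E: np.ndarray
    A: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (len(self.q) == len(self.I) == len(self.E)):
            raise ValueError("q, I and E must have equal length")

    @property
    def n_points(self) -> int:
        return len(self.q)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntegratedCurve):
            return NotImplemented
        return (
            np.array_equal(self.q, other.q)
            and np.array_equal(self.I, other.I)
            and np.array_equal(self.E, other.E)
        )


def build_binning(
    qmap: QMap,
    mask: np.ndarray,
    pix_per_rad_element: float,
    geom: GeometrySpec,
) -> RadialBinning:
    """Derive the radial binning from the q map and the static mask.

    The number of bins is ``floor(r_max / pix_per_rad_element)`` (at least 1),
    where ``r_max`` is the largest unmasked pixel distance from the beam
    center expressed in mean-pixel units, and the bins are uniform in q from 0
    to the largest unmasked q.  This reproduces radial steps of
    ``pix_per_rad_element`` detector pixels for an untilted detector and stays
    well defined under tilt.
    """
    if pix_per_rad_element <= 0:
        raise ValueError("pix_per_rad_element must be positive")
    unmasked = ~np.asarray(mask, dtype=bool)
    if not unmasked.any():
        raise ValueError("cannot build a binning: every pixel is masked")
    nv, nh = geom.image_size
    rows, cols = np.meshgrid(np.arange(nv, dtype=float), np.arange(nh, dtype=float), indexing="ij")
    # radius in mean-pixel units (anisotropic pixels use the mean pitch)
    pv, ph = geom.pixel_size
    mean_pix_mm = 0.5 * (pv + ph) * 1e-3
    dx = (cols - geom.beamcenter[1]) * ph * 1e-3
    dy = (rows - geom.beamcenter[0]) * pv * 1e-3
    r_px = np.hypot(dx, dy) / mean_pix_mm
    r_max = float(r_px[unmasked].max())
    n_bins = max(1, int(r_max / pix_per_rad_element))
    q_max = float(qmap.q[unmasked].max())
    if q_max <= 0:
        q_max = np.finfo(float).tiny
    edges = np.linspace(0.0, q_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialBinning(n_bins=n_bins, q_centers=centers, q_edges=edges)


def build_weight_matrix(
    geom: GeometrySpec,
    wavelength: float,
    binning: RadialBinning,
    mask: np.ndarray,
    oversampling: int = 1,
) -> WeightMatrix:
    """Build the sparse weighting matrix ``C`` and area vector ``A``.

    A pixel participates iff it is unmasked and its center q lies within the
    binning span.  With oversampling factor ``k`` its ``k²`` subpixel centers
    each deposit ``1/k²`` into the bin containing their q (indices clipped to
    the binning span), so every participating column sums to exactly 1.
    ``k = 1`` degenerates to binary nearest-bin assignment of pixel centers.
    """
    k = int(oversampling)
    if k < 1:
        raise ValueError("oversampling must be an integer >= 1")
    mask = np.asarray(mask, dtype=bool)
    nv, nh = geom.image_size
    if mask.shape != (nv, nh):
        raise ValueError(f"mask shape {mask.shape} does not match image size {(nv, nh)}")
    edges = binning.q_edges
    qc = build_qmap(geom, wavelength).q
    in_range = (~mask) & (qc >= edges[0]) & (qc <= edges[-1])
    rr, cc = np.nonzero(in_range)
    flat = rr * nh + cc
    n_pix = nv * nh

    if rr.size == 0:
        C = sp.csr_matrix((binning.n_bins, n_pix))
        return WeightMatrix(C=C, A=np.zeros(binning.n_bins), image_shape=(nv, nh))

    w = 1.0 / (k * k)
    offsets = (np.arange(k) + 0.5) / k - 0.5
    rows_out = []
    cols_out = []
    for dv in offsets:
        for dh in offsets:
            q_sub = build_qmap(geom, wavelength, rr + dv, cc + dh).q
            bins = np.searchsorted(edges, q_sub, side="right") - 1
            np.clip(bins, 0, binning.n_bins - 1, out=bins)
            rows_out.append(bins)
            cols_out.append(flat)
    data = np.full(rr.size * k * k, w)
    C = sp.coo_matrix(
        (data, (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(binning.n_bins, n_pix),
    ).tocsr()
    C.sum_duplicates()
    A = np.asarray(C.sum(axis=1)).ravel()
    return WeightMatrix(C=C, A=A, image_shape=(nv, nh))


def bin_areas(W: WeightMatrix) -> np.ndarray:
    """Effective per-bin area ``A = C · 1`` (sum of pixel weights per bin)."""
    return np.asarray(W.C @ np.ones(W.C.shape[1])).ravel()


def poisson_errors(I: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Standard error of the bin mean for Poisson counts: ``E = sqrt(I / A)``.

    ``A`` pixels with mean ``I`` counts each sum to a Poisson variable of
    variance ``A·I``; the mean over the bin therefore has standard deviation
    ``sqrt(A·I)/A = sqrt(I/A)``.
    """
    I = np.asarray(I, dtype=float)
    A = np.asarray(A, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.sqrt(np.where(A > 0, I / np.where(A > 0, A, 1.0), 0.0))
    return np.where(I == 0, 0.0, E)


def integrate_frame(
    frame: np.ndarray,
    W: WeightMatrix,
    binning: RadialBinning,
) -> IntegratedCurve:
    """Reduce one detector frame to an :class:`IntegratedCurve`.

    Pixels with negative counts (detector sentinel values such as −1/−2 gap
    markers) or non-finite values are excluded for this frame only, on top of
    the static mask baked into ``W``.  Bins with zero effective area are
    omitted from the output.
    """
    frame = np.asarray(frame)
    if frame.shape != W.image_shape:
        raise ValueError(f"frame shape {frame.shape} does not match calibration {W.image_shape}")
    p = frame.ravel().astype(float)
    valid = np.isfinite(p) & (p >= 0)
    if valid.all():
        num = W.C @ p
        den = W.A
    else:
        num = W.C @ np.where(valid, p, 0.0)
        den = np.asarray(W.C @ valid.astype(float)).ravel()
    emit = den > 0
    I = num[emit] / den[emit]
    E = poisson_errors(I, den[emit])
    return IntegratedCurve(q=binning.q_centers[emit], I=I, E=E, A=den[emit])


def write_chi(curve: IntegratedCurve, path, header_lines: tuple[str, ...] = ()) -> None:
    """Write a three-column (q, I, E) plain-text ``.chi`` file."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# q[nm^-1]  I[counts/pixel]  E\n")
        fh.write(f"# points: {curve.n_points}\n")
        for q, i, e in zip(curve.q, curve.I, curve.E):
            fh.write(f"{q:.12e} {i:.12e} {e:.12e}\n")


def read_chi(path) -> IntegratedCurve:
    """Read a ``.chi`` file written by :func:`write_chi`."""
    qs, Is, Es = [], [], []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            qs.append(float(parts[0]))
            Is.append(float(parts[1]))
            Es.append(float(parts[2]))
    return IntegratedCurve(q=np.array(qs), I=np.array(Is), E=np.array(Es))
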