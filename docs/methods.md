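# Methods

This note records the models, conventions and numerical choices behind
`azimint`, and what the synthetic test substrate does and does not establish
about real detector data.

## Geometry model

Coordinates are (row, column) = (vertical, horizontal), 0-based, origin at
the top-left stored pixel. Pixels are evaluated at their centers; the beam
center lives in the same center-based frame and may be fractional. The
azimuth ψ is measured from the rightward horizontal axis, counter-clockwise
as seen looking downstream, with "up" meaning decreasing row index.

A tilted detector is modelled as a rigid rotation of the detector plane (and
the pixel grid with it) by the tilt angle τ about the in-plane axis at
azimuth φ + 90°, where φ is the FIT2D-style tilt rotation (direction of
steepest tilt). A pixel at in-plane polar coordinates (r, ψ) about the beam
center then sits at 3D position BC + r·û(ψ) with û·ẑ = sin α and

    sin α = sin τ · cos(ψ − φ).

α is the whole tilt story per pixel: it vanishes on the tilt axis, equals ±τ
along the steepest direction, and is identically zero for τ = 0. The
sample–pixel triangle gives the scattered light path and scattering angle

    l = √(d² + r² + 2 d r sin α),    cos 2θ = (d + r sin α)/l,

and q = (4π/λ)·sin θ, reported in nm⁻¹ (λ is carried in Å, hence the
factor 10). `d` is the sample-to-beam-center distance along the beam, so
l < d is possible on the side of the detector tipped toward the sample.

Sign convention: positive τ tips the detector region at azimuth ψ = φ
*downstream* (away from the sample). The convention is arbitrary up to the
sign of τ; what is not arbitrary is internal consistency, which is enforced
by testing the closed form against an independent 3D ray construction
(`synthetic.oracle_q_3d`, built on scipy rotations rather than the formulas
above) to 10⁻⁶ relative over randomized (φ, τ ≤ 30°).

2θ is computed via `arccos` of the on-axis projection rather than a tangent
form: it is well-behaved at r = 0 and needs no quadrant bookkeeping. The
relation φ = χ + 90° connects φ to the GSAS-II tilt-plane angle χ; no
GSAS-II import is provided.

## Radial binning and the weighting matrix

Bins are uniform in q from 0 to the largest unmasked pixel q. The bin count
is ⌊r_max / w⌋ (minimum 1), where w is the configured radial step in
detector-pixel units and r_max the largest unmasked pixel radius in
mean-pixel units (the v/h average covers anisotropic pixels). At zero tilt
this reproduces radial steps of w pixels exactly; under tilt, binning in q
(computed per subpixel through the full geometry) remains well defined where
pixel radius would not be.

The weighting matrix C (bins × pixels, CSR) is built once per calibration
and reused across frames. With oversampling factor k, each participating
pixel's k×k subpixel centers each deposit 1/k² into the bin containing their
q. Two edge rules make the matrix exactly intensity-conserving for every k:

* a pixel participates iff it is unmasked and its *center* q lies within the
  binning span;
* subpixel bin indices are clipped to the span, so boundary subpixels of a
  participating pixel cannot leak out.

Hence every participating column sums to exactly 1, Σ_j A_j = number of
participating pixels, and Σ_j A_j·I_j equals their total counts to rounding.
Masked pixels are structurally empty columns — exclusion semantics without
NaN poisoning. Per-frame exclusions (negative sentinel counts such as the
−1/−2 gap markers of photon-counting modules, and non-finite values) are
handled at integration time by re-deriving the effective area A = C·valid
for that frame. Bins with zero effective area are omitted from the output
curve rather than emitted as NaN rows, keeping `.chi` files plot-ready.

## Error model

Photon counts are Poisson. A bin averaging A pixels of mean I has variance
A·I/A² = I/A, so the reported error of the mean is E = √(I/A), with E = 0
where I = 0. This is calibrated by Monte-Carlo in the acceptance script:
over 10 000 frames of i.i.d. Poisson(9) pixels in a single bin of area 100,
the empirical standard deviation of the bin mean reproduces √(9/100) = 0.3
to within sampling error. The model ignores detector read-out effects
(photon counters have none to first order) and any inter-pixel correlation.

## GISAXS slices

Slices are line cuts in *detector* coordinates: for an x slice at row
position p with margin m, rows p−m … p+m (thickness 2m+1) are averaged per
column over unmasked, non-negative pixels; E = √(I/A) with A the per-point
valid count; fully excluded points are omitted. The axis is the in-detector
scattering-vector component q_H or q_V via the zero-tilt mapping
q = ±(4π/λ)·sin(atan(Δ/d)/2), antisymmetric about the beam center. Detector
tilt, the beam incidence angle and the Ewald-sphere distortion are
deliberately ignored — the cuts are quick-look monitors, valid at small
angles or for in-plane-disordered samples; precise reciprocal-space mapping
belongs to dedicated GISAXS software. The InPlane/Vertical "plane" attribute
is orientation bookkeeping only and never changes the numerics. The
exclusion of negative sentinel counts mirrors the radial integrator so gap
markers cannot poison slice means.

## Classifiers

The per-image integral parameters are window-bound quick-look monitors, not
extrapolated structural invariants: over the configured [q₁, q₂],

* integral intensity ∫I dq,
* invariant ∫q²I dq (Porod invariant over the window),
* correlation length l_c = π·∫qI dq / ∫q²I dq (nm).

Integrals are trapezoidal over the curve points inside the window; no
q → 0/∞ extrapolation is attempted, so absolute values depend on the window
while trends across a kinetic series do not. Fewer than two in-window points,
or a vanishing invariant, yield NaN flagged by `ClassifierRecord.valid`.
These are the standard textbook definitions; adopting them (and the
trapezoid rule) is a package choice. Acquisition time is read from the TIFF
DateTime tag when present (photon-counting detectors embed it), falling back
to the file modification time; the history's data-set selector keys on the
filename prefix before the trailing frame number, matching serial-acquisition
naming at beamlines.

## Calibration and masks

The calibration is a JSON document (lengths: detector distance mm, pixel
size µm, wavelength Å, q windows nm⁻¹, angles degrees) with one binning
configuration per mask entry. Unknown extra keys are preserved verbatim on
round-trip for forward compatibility. Validation errors name the offending
key. The FIT2D `.msk` dialect implemented: 1024-byte header starting
`b"MASK"`, width/height as little-endian int32 at offsets 16/20, bit-packed
rows LSB-first padded to 4-byte multiples; a set bit excludes the pixel.
Image-file masks (single-channel TIFF/PNG) exclude nonzero pixels. Multiple
masks combine by OR of exclusions.

## Pipeline

The picture queue is a de-duplicating FIFO: each distinct path is accepted
once per queue lifetime, making processing exactly-once no matter how many
walkers or feeders race. Workers are threads — the reduction is dominated by
numpy/scipy matvec work that releases the GIL, and worker count never
affects output bytes, only throughput. A corrupt frame increments the
failure counter and is logged; the pool continues. The classifier history
sorts on insertion by acquisition time, so online (out-of-order completion)
and offline runs build identical histories. Completed paths are recorded in
a sidecar text file in the output directory; re-runs skip them unless a
reintegration is requested.

Online mode uses a TCP pub/sub link carrying newline-delimited JSON
`{"command": "new file", "argument": path}` events (default port 5555). The
feeder announces a file only once its size is unchanged across two polls
(100 ms class spacing) — the completeness rule that keeps the server off
half-written images. The control channel is a minimal HTTP endpoint with
four commands (`new`, `reintegrate`, `abort`, `status`); configuring a
shared secret (via `~/.saxsdognetwork`) enables HMAC-SHA256 authentication
of request bodies. Message-body encryption is out of scope.

## Synthetic substrate and its limits

All tests and the acceptance script run on generated data: flat fields,
annuli, and isotropic frames prescribed by an analytic radial profile
(sphere form factor, smooth trigonometric profiles), optionally
Poisson-sampled under a fixed seed. The default synthetic geometry —
256×256 (or smaller) frames of 172 µm pixels at d = 1000 mm, λ = 1.54 Å —
keeps the full suite in tens of seconds while matching real pixel pitch and
q range; the acceptance pipeline runs use 200 frames of 32×32 so the
offline/online byte-comparison triad stays fast. What passing shows: the
algebra (geometry, rebinning, conservation, error propagation, queue
semantics) is correct on data obeying the stated models. What it does not
show: robustness to real-detector artifacts — flat-field texture, realistic
module-gap layouts, point-spread, timestamp quirks of specific detector
firmware — nor absolute-intensity calibration, which the package does not
attempt.

## Known limitations

* Slice q axes ignore tilt and incidence angle (by design, see above).
* No polarization, solid-angle, flat-field or dark corrections.
* No azimuthally-resolved ("cake") regrouping.
* The oversampling clip rule slightly biases the outermost bin when a
  participating pixel straddles the q_max edge; conservation is exact, the
  bin-center assignment there is approximate.
* The q-domain binning choice coincides with detector-radius binning only at
  zero tilt.
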