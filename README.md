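# azimint

Real-time azimuthal integration of 2D scattering-detector images into 1D
intensity curves, for small-angle X-ray scattering (SAXS) at beamlines and
laboratory instruments.

Synchrotron SAXS detectors (Pilatus-style photon counters, ~1 Mpixel) produce
hundreds of frames per second during *in situ* experiments. Each 2D frame must
be reduced to a 1D curve I(q) — with a proper counting-statistics error band —
before anyone can judge whether the experiment is working. `azimint` does that
reduction online: a watch-folder or networked feeder announces frames, a pool
of workers integrates them, and per-image scalar classifiers give a live
quick-look at the kinetics without any model fitting.

## The reduction in brief

Each detector pixel is assigned a scattering-vector magnitude
q = (4π/λ)·sin θ, where 2θ is its scattering angle. For a detector tilted by
τ (tilt rotation φ, FIT2D convention) the 3D geometry reduces to a per-pixel
2D problem through a single distortion angle α:

    sin α = sin τ · cos(ψ − φ)
    l     = √(d² + r² + 2 d r sin α)          (scattered light path)
    cos 2θ = (d + r sin α) / l

with r, ψ the pixel's in-detector polar coordinates about the beam center and
d the sample–detector distance. This closed form is validated in the test
suite against an independent 3D ray construction.

The integration itself is a sparse matrix–vector product. The flattened image
**p** is multiplied by a weighting matrix **C** (bins × pixels):

    I = (C·p) ⊘ A,   A = C·1,   E = √(I ⊘ A)

**A** is the per-bin effective area and **E** the standard error of the bin
mean for Poisson-distributed counts. Anti-aliasing: every pixel is subdivided
into k×k subpixels, each depositing weight 1/k² into the bin containing its
q — pixels straddling a bin border are shared fractionally, column sums stay
exactly 1, and total intensity is conserved for every k. Masked pixels
(FIT2D `.msk` bitmaps or image masks) are structurally absent columns;
negative sentinel counts (module-gap markers) are excluded per frame.

On top of the radial reduction the package provides GISAXS line slices in
detector coordinates (q_H / q_V, no Ewald-sphere correction) and three
per-image classifiers over a configured q window: the integral intensity
∫I dq, the (window) Porod invariant ∫q²I dq, and the correlation length
l_c = π·∫qI dq / ∫q²I dq.

## Worked example

Generate a small synthetic data set (sphere form factor frames + beamstop
mask + calibration) and reduce it:

```sh
$ azimint make-fixtures demo --n-frames 3
wrote 3 frames + mask + calibration to demo
$ azimint watch demo --calibration demo/calibration.json --out demo/out --threads 2
completed=3 failed=0
$ azimint integrate demo/sphere_00000.tif -c demo/calibration.json -o demo/out
demo/sphere_00000.tif: integral=182.897 invariant=29.5079 l_c=7.29933 nm
```

Each frame yields a three-column `.chi` file (q [nm⁻¹], I [counts/pixel], E)
plus one file per configured slice. The printed classifiers summarize the
curve over the calibration's [q-start, q-stop] window: the correlation length
of ≈ 7.3 nm is the quick-look size scale of the 5 nm-radius spheres the
fixture prescribes (l_c is a π∫qI/∫q²I average over the window, not a radius
fit — for growing particles it is its *trend* that carries the information).

The same engine runs as a long-lived networked service
(`azimint serve` + `azimint feed`): the feeder publishes
`{"command": "new file", "argument": <path>}` events once a frame's size is
stable (default port 5555), and the server accepts `new` / `reintegrate` /
`abort` / `status` commands over a minimal HTTP control interface, optionally
HMAC-authenticated with a shared secret from `~/.saxsdognetwork`. The
`examples/` directory holds short narrative scripts for every capability.

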