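"""Effect of detector tilt on the per-pixel q map.

Compares the q map of a detector tilted by tau = 20 deg (tilt rotation
phi = 30 deg) with the untilted map and with an independent 3D
ray-construction of the same geometry.
"""

import numpy as np

from azimint.geometry import build_qmap
from azimint.synthetic import DEFAULT_WAVELENGTH, default_geometry, oracle_q_3d

flat = default_geometry((256, 256))
tilted = default_geometry((256, 256), tilt_rotation=30.0, tilt_angle=20.0)

q_flat = build_qmap(flat, DEFAULT_WAVELENGTH).q
q_tilt = build_qmap(tilted, DEFAULT_WAVELENGTH).q
q_ray = oracle_q_3d(tilted, DEFAULT_WAVELENGTH)

shift = (q_tilt - q_flat) / np.where(q_flat > 0, q_flat, 1.0)
print(f"max |relative q shift| from the tilt: {np.abs(shift).max() * 100:.2f} %")
print(f"q shift at frame centre-right edge:   {shift[128, 255] * 100:+.2f} %")
print(f"q shift at frame centre-top edge:     {shift[0, 128] * 100:+.2f} %")
dev = np.abs(q_tilt - q_ray) / np.maximum(q_ray, 1e-12)
print(f"max relative deviation from the 3D ray construction: {dev.max():.2e}")
# The tilt compresses q on the side tipped toward the sample and stretches it
# on the far side; the closed-form map agrees with explicit ray tracing to
# numerical precision.
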