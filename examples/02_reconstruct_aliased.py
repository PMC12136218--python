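"""Recover a velocity field that aliases beyond the VENC limit.

The phantom's waveform peaks at ~1.6 x VENC, so the encoded phase wraps
during systole; a static background plane (constant offset + in-plane ramp)
is added on top.  Temporal unwrapping undoes the wraps voxel-by-voxel and a
plane fit over static tissue removes the background; the reconstructed
velocity then matches the ground truth to numerical precision.
"""

import numpy as np

from csfpulse import (
    PhantomSpec,
    generate_phantom,
    phase_to_velocity,
    reconstruct_velocity,
)

spec = PhantomSpec(
    waveform_harmonics=((0.8, 0.0, np.pi / 2), (13.6, 1.0, 0.0), (4.0, 2.0, 0.0)),
    background_offset_rad=0.3,
    background_ramp=(0.004, -0.003),
)
_, phase, truth = generate_phantom(spec)

peak_true = np.abs(truth.velocity_true).max()
print(f"peak true velocity      : {peak_true:.2f} cm/s (venc = 10 cm/s)")

naive = phase_to_velocity(phase)
err_naive = np.abs(naive.values - truth.velocity_true).max()
print(f"naive decode max error  : {err_naive:.2f} cm/s (aliasing + background)")

static = np.ones(truth.mask_true.mask.shape, dtype=bool) & ~truth.mask_true.mask
vel = reconstruct_velocity(phase, static_mask=static)
err = np.abs(vel.values - truth.velocity_true).max()
print(f"reconstructed max error : {err:.2e} cm/s after unwrap + plane fit")

# The naive decode is off by tens of cm/s (a 2*venc alias plus the decoded
# background); the full reconstruction is exact to floating-point noise.
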