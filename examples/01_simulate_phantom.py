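"""Simulate a cardiac-gated phase-contrast acquisition of the spinal canal.

Builds the default digital phantom (64 x 64 single slice, VENC 10 cm/s,
40 cardiac phases over a 453 ms cycle) and prints the ground-truth flow
waveform summary: the cranial (positive) and caudal (negative) lobe volumes
in mm^3/s x cardiac-phase and the phase at which flow reverses from caudal
to cranial.
"""

import numpy as np

from csfpulse import PhantomSpec, find_flow_reversal, generate_phantom

magnitude, phase, truth = generate_phantom(PhantomSpec(seed=0))
m = truth.metrics_true

print(f"grid: {phase.values.shape[0]} x {phase.values.shape[1]}, "
      f"{phase.values.shape[2]} cardiac phases")
print(f"canal ROI: {truth.mask_true.n_voxels} voxels, "
      f"{truth.mask_true.area_mm2:.1f} mm^2")
print(f"cranial flow volume : {m.cranial_volume:8.2f} mm^3/s x phase")
print(f"caudal flow volume  : {m.caudal_volume:8.2f} mm^3/s x phase")
print(f"net stroke volume   : {m.net_stroke:8.2f} mm^3/s x phase")
print(f"peak flow rate      : {m.peak:8.2f} mm^3/s")
upward = [c for _, b, c in find_flow_reversal(truth.waveform_true)
          if truth.waveform_true.q[b] > 0]
print(f"caudal->cranial reversal at cardiac phase {upward[0]:.2f} of 40")
print(f"peak phase value    : {np.abs(phase.values).max():.3f} rad (< pi, "
      f"no aliasing at this flow speed)")

# The cranial lobe is ~2.5x the caudal lobe: net CSF movement toward the
# head over each heartbeat, with the reversal landing between phases 6 and 7.
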