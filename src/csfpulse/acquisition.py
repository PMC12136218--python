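"""Acquisition geometry and velocity-encoding arithmetic.

Phase-contrast MRI encodes through-plane velocity into the signal phase:
a voxel moving at velocity ``v`` (cm/s) acquires phase ``phi = pi * v / venc``
radians, where ``venc`` is the velocity-encoding limit of the bipolar
gradients.  Velocities of magnitude ``venc`` map to +/-pi; anything beyond
wraps (aliases) by multiples of 2*pi.  Decoding is the inverse:
``v = phi * venc / pi``.

Sign convention used throughout the package: positive velocity and flow are
cranial (toward the head), negative are caudal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class AcquisitionParams:
    """Cardiac-gated phase-contrast acquisition parameters.

    Defaults are the single-slice spinal-canal protocol: VENC 10 cm/s,
    0.47 x 0.47 mm in-plane voxels, 3.1 mm slice, 40 cardiac phases over a
    nominal 453 ms cycle (retrospective ECG gating, uniformly spaced frames).

    Attributes
    ----------
    venc : float
        Velocity-encoding limit, cm/s.
    voxel_dx, voxel_dy : float
        In-plane voxel size, mm.
    slice_dz : float
        Slice thickness, mm.
    n_phases : int
        Reconstructed cardiac phases per heartbeat.
    cycle_ms : float
        Nominal cardiac-cycle duration, ms.
    """

    venc: float = 10.0
    voxel_dx: float = 0.47
    voxel_dy: float = 0.47
    slice_dz: float = 3.1
    n_phases: int = 40
    cycle_ms: float = 453.0

    def __post_init__(self) -> None:
        if not self.venc > 0:
            raise ValueError(f"venc must be > 0, got {self.venc}")
        if self.n_phases < 2:
            raise ValueError(f"n_phases must be >= 2, got {self.n_phases}")
        for name in ("voxel_dx", "voxel_dy", "slice_dz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.cycle_ms > 0:
            raise ValueError(f"cycle_ms must be > 0, got {self.cycle_ms}")

    @property
    def dt_ms(self) -> float:
        """Duration of one cardiac phase, ms."""
        return self.cycle_ms / self.n_phases

    @property
    def dt_s(self) -> float:
        """Duration of one cardiac phase, s."""
        return self.dt_ms / 1000.0

    @property
    def voxel_area_mm2(self) -> float:
        """In-plane voxel area, mm^2."""
        return self.voxel_dx * self.voxel_dy


def wrap_phase(phi: np.ndarray | float) -> np.ndarray:
    """Wrap phase to the half-open interval [-pi, pi).

    +pi maps to -pi, matching two's-complement phase storage on scanners
    (v = +venc encodes as -pi).
    """
    return np.mod(np.asarray(phi, dtype=float) + np.pi, TWO_PI) - np.pi
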