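"""In-memory containers for cardiac-gated image series.

All series are (nx, ny, n_phases) float arrays with the cardiac phase on the
last axis, plus the acquisition parameters they were measured under.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionParams


def _check_shape(values: np.ndarray, params: AcquisitionParams) -> None:
    if values.ndim != 3:
        raise ValueError(f"expected (nx, ny, n_phases) array, got shape {values.shape}")
    if values.shape[2] != params.n_phases:
        raise ValueError(
            f"series has {values.shape[2]} cardiac phases but params.n_phases "
            f"= {params.n_phases}"
        )


@dataclass
class PhaseSeries:
    """Per-voxel phase (rad) over the cardiac cycle.

    ``wrapped`` is True for raw scanner output (all values in [-pi, pi));
    after temporal unwrapping it is False and values may exceed that range.
    ``unreliable`` marks voxels whose unwrapped excursion exceeded the
    configured limit (set by :func:`csfpulse.recon.unwrap_temporal`).
    """

    values: np.ndarray
    params: AcquisitionParams
    wrapped: bool = True
    unreliable: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.values, self.params)
        if self.wrapped and (
            np.any(self.values < -np.pi) or np.any(self.values >= np.pi)
        ):
            raise ValueError("wrapped phase values must lie in [-pi, pi)")


@dataclass
class MagnitudeSeries:
    """Per-voxel signal magnitude (arbitrary units) over the cardiac cycle."""

    values: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.values, self.params)
        if np.any(self.values < 0):
            raise ValueError("magnitude values must be >= 0")


@dataclass
class VelocitySeries:
    """Per-voxel velocity (cm/s, positive = cranial) over the cardiac cycle."""

    values: np.ndarray
    params: AcquisitionParams
    unwrapped: bool = False
    background_corrected: bool = False
    unreliable: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.values, self.params)
        if (
            not self.unwrapped
            and not self.background_corrected
            and np.any(np.abs(self.values) > self.params.venc)
        ):
            raise ValueError(
                "velocities from wrapped phase cannot exceed venc; "
                "got |v| > venc without unwrapped=True"
            )
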