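"""Flow-rate waveform integration and the six CSF flow dynamics metrics.

The flow rate at cardiac phase k is the velocity integrated over the
region-of-interest cross-section:

    q[k] = sum_{voxels in ROI} v[voxel, k] * 10 * voxel_area        [mm^3/s]

(velocity in cm/s, voxel area in mm^2; the factor 10 converts cm/s to mm/s).
Summation is per voxel, not mean-velocity-times-total-area, so partial-lumen
masks weight each voxel by its own velocity.

The six metrics summarising a waveform over one cardiac cycle:

* cranial flow volume   = sum of the positive part of q
* caudal flow volume    = sum of the negative part of q (reported positive)
* net stroke volume     = cranial - caudal  (= plain sum of q)
* absolute stroke volume = cranial + caudal (= sum of |q|)
* amplitude of flow rate = max(q) - min(q)   (peak-to-peak)
* peak flow rate         = max |q|

The four volume metrics are phase-sums in mm^3/s x cardiac-phase (the
conventional reporting unit for gated series); multiplying by the per-phase
duration dt (s) converts them to true volumes in mm^3, and both scales are
carried on :class:`FlowMetrics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import VelocitySeries

CM_PER_S_TO_MM_PER_S = 10.0

#: Canonical metric names, in reporting order.
METRIC_NAMES = (
    "cranial_volume",
    "caudal_volume",
    "net_stroke",
    "absolute_stroke",
    "amplitude",
    "peak",
)


@dataclass(frozen=True)
class ROIMask:
    """Region of interest in the imaging plane (e.g. the spinal-canal lumen).

    Attributes
    ----------
    mask : np.ndarray
        Boolean (nx, ny) array, True inside the ROI.
    voxel_area_mm2 : float
        In-plane voxel area, mm^2.
    """

    mask: np.ndarray
    voxel_area_mm2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D (nx, ny)")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        if not self.voxel_area_mm2 > 0:
            raise ValueError("voxel_area_mm2 must be > 0")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        """Cross-sectional area of the ROI, mm^2."""
        return self.n_voxels * self.voxel_area_mm2


@dataclass
class FlowWaveform:
    """Flow rate per cardiac phase inside the ROI.

    ``q`` is in mm^3/s (positive = cranial); ``dt_ms`` is the duration of one
    cardiac phase in ms.
    """

    q: np.ndarray
    dt_ms: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1 or self.q.size < 2:
            raise ValueError("waveform must be a 1-D array of >= 2 phases")
        if not self.dt_ms > 0:
            raise ValueError("dt_ms must be > 0")

    @property
    def n_phases(self) -> int:
        return self.q.size

    @property
    def dt_s(self) -> float:
        return self.dt_ms / 1000.0


@dataclass(frozen=True)
class FlowMetrics:
    """The six scalar summaries of a flow waveform.

    Volume metrics (``cranial_volume``, ``caudal_volume``, ``net_stroke``,
    ``absolute_stroke``) are phase-sums in mm^3/s x cardiac-phase; the
    ``*_mm3`` properties give the time-integrated equivalents (x dt in s).
    ``amplitude`` and ``peak`` are rates in mm^3/s.
    """

    cranial_volume: float
    caudal_volume: float
    net_stroke: float
    absolute_stroke: float
    amplitude: float
    peak: float
    dt_ms: float

    @property
    def dt_s(self) -> float:
        return self.dt_ms / 1000.0

    @property
    def cranial_volume_mm3(self) -> float:
        return self.cranial_volume * self.dt_s

    @property
    def caudal_volume_mm3(self) -> float:
        return self.caudal_volume * self.dt_s

    @property
    def net_stroke_mm3(self) -> float:
        return self.net_stroke * self.dt_s

    @property
    def absolute_stroke_mm3(self) -> float:
        return self.absolute_stroke * self.dt_s

    def as_dict(self) -> dict[str, float]:
        """Both unit systems, flat, for serialization."""
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d.update(
            {
                f"{name}_mm3": getattr(self, f"{name}_mm3")
                for name in METRIC_NAMES[:4]
            }
        )
        d["dt_ms"] = self.dt_ms
        return d

    def values(self) -> np.ndarray:
        """The six phase-sum/rate values in canonical order."""
        return np.array([getattr(self, name) for name in METRIC_NAMES])


def compute_waveform(velocity: VelocitySeries, roi: ROIMask) -> FlowWaveform:
    """Integrate a velocity series over the ROI into a flow-rate waveform."""
    if roi.mask.shape != velocity.values.shape[:2]:
        raise ValueError(
            f"ROI mask shape {roi.mask.shape} does not match image plane "
            f"{velocity.values.shape[:2]}"
        )
    q = (
        velocity.values[roi.mask, :].sum(axis=0)
        * CM_PER_S_TO_MM_PER_S
        * roi.voxel_area_mm2
    )
    return FlowWaveform(q=q, dt_ms=velocity.params.dt_ms)


def compute_metrics(w: FlowWaveform, peak_cranial_only: bool = False) -> FlowMetrics:
    """Compute the six CSF flow metrics of a waveform.

    ``peak_cranial_only`` restricts the peak to the cranial (positive) lobe;
    by default the peak is the maximum absolute flow regardless of direction.
    """
    q = w.q
    cranial = float(np.sum(np.maximum(q, 0.0)))
    caudal = float(np.sum(np.maximum(-q, 0.0)))
    peak_pool = np.maximum(q, 0.0) if peak_cranial_only else np.abs(q)
    return FlowMetrics(
        cranial_volume=cranial,
        caudal_volume=caudal,
        net_stroke=float(np.sum(q)),
        absolute_stroke=float(np.sum(np.abs(q))),
        amplitude=float(np.max(q) - np.min(q)),
        peak=float(np.max(peak_pool)),
        dt_ms=w.dt_ms,
    )


def smooth_waveform(w: FlowWaveform, window: int = 3) -> FlowWaveform:
    """Optional cyclic moving-average smoothing (off by default everywhere)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return FlowWaveform(q=w.q.copy(), dt_ms=w.dt_ms)
    half = window // 2
    padded = np.concatenate([w.q[-half:], w.q, w.q[:half]])
    kernel = np.full(window, 1.0 / window)
    return FlowWaveform(q=np.convolve(padded, kernel, mode="valid"), dt_ms=w.dt_ms)


def find_flow_reversal(w: FlowWaveform) -> list[tuple[int, int, float]]:
    """Locate flow-direction reversals (zero crossings) in a cyclic waveform.

    Returns a list of ``(k, k_next, crossing_phase)`` tuples: the waveform
    changes sign between adjacent phases ``k`` and ``k_next`` (cyclically);
    ``crossing_phase`` is the fractional phase index of the interpolated zero.
    A constant-sign waveform returns an empty list.
    """
    q = w.q
    n = q.size
    out: list[tuple[int, int, float]] = []
    for k in range(n):
        k_next = (k + 1) % n
        a, b = q[k], q[k_next]
        if a * b < 0:
            frac = a / (a - b)  # linear interpolation, in (0, 1)
            out.append((k, k_next, k + float(frac)))
        elif a == 0.0 and b != 0.0:
            # exact zero sample: report the sample itself as the crossing if
            # the neighbours straddle zero
            prev = q[(k - 1) % n]
            if prev * b < 0:
                out.append(((k - 1) % n, k_next, float(k)))
    return out
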