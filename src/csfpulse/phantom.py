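"""Digital phantom: cardiac-gated phase-contrast MRI series with known truth.

The forward model inverts the reconstruction chain.  A pulsatile velocity
field is laid over a circular "spinal canal" in an otherwise static plane;
velocity is encoded into phase (``phi = pi * v / venc``, wrapped to
[-pi, pi)), a static background phase (constant offset + linear in-plane
ramp) is added, and Gaussian phase noise / Rician magnitude noise is applied.
The returned :class:`GroundTruth` carries the noiseless velocity field, the
ROI-integrated flow waveform and its six metrics, so every downstream stage
can be validated to machine precision on clean inputs.

The default waveform (DC + two harmonics, calibrated constants below) makes
the default 64 x 64 phantom's ROI-integrated flow reproduce the canonical
spinal-canal profile: a short, deep caudal (systolic) lobe of about
90 mm^3/s x cardiac-phase ending between phases 6 and 7, and a long cranial
(diastolic) lobe of about 225 mm^3/s x cardiac-phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import TWO_PI, AcquisitionParams, wrap_phase
from .flow import ROIMask, FlowMetrics, FlowWaveform, compute_metrics, compute_waveform
from .series import MagnitudeSeries, PhaseSeries, VelocitySeries

# Centreline-velocity waveform for the default phantom, as
# (amplitude cm/s, frequency cycles-per-cardiac-cycle, phase offset rad).
# Frequency 0 with phase pi/2 is the DC (mean-flow) term.  Calibrated offline
# once against the target lobe volumes above; frozen, never fitted at run
# time.  Peak centreline velocity ~0.15 cm/s, far below the 10 cm/s VENC.
DEFAULT_HARMONICS: tuple[tuple[float, float, float], ...] = (
    (0.038817, 0.0, np.pi / 2.0),
    (0.129312, 1.0, 4.798814),
    (0.022362, 2.0, 5.269463),
    (0.000337, 3.0, 2.862917),
)

MAGNITUDE_CANAL = 100.0  # bright CSF lumen in the magnitude image
MAGNITUDE_TISSUE = 15.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, waveform and corruption parameters of the image phantom.

    ``canal_center_mm`` defaults to the grid centre.  ``background_ramp`` is
    (rad per voxel in x, rad per voxel in y); together with
    ``background_offset_rad`` it forms the static background phase plane.
    """

    grid_nx: int = 64
    grid_ny: int = 64
    canal_center_mm: tuple[float, float] | None = None
    canal_radius_mm: float = 2.35
    waveform_harmonics: tuple[tuple[float, float, float], ...] = DEFAULT_HARMONICS
    velocity_profile: str = "parabolic"
    background_offset_rad: float = 0.0
    background_ramp: tuple[float, float] = (0.0, 0.0)
    noise_sd_phase: float = 0.0
    noise_sd_magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid must be at least 2 x 2")
        if not self.canal_radius_mm > 0:
            raise ValueError("canal_radius_mm must be > 0")
        if self.velocity_profile not in ("plug", "parabolic"):
            raise ValueError(
                f"velocity_profile must be 'plug' or 'parabolic', "
                f"got {self.velocity_profile!r}"
            )
        if self.noise_sd_phase < 0 or self.noise_sd_magnitude < 0:
            raise ValueError("noise SDs must be >= 0")
        if len(self.waveform_harmonics) == 0:
            raise ValueError("at least one waveform harmonic is required")

    def center_mm(self, params: AcquisitionParams) -> tuple[float, float]:
        if self.canal_center_mm is not None:
            return self.canal_center_mm
        return (
            self.grid_nx * params.voxel_dx / 2.0,
            self.grid_ny * params.voxel_dy / 2.0,
        )

    def validate_geometry(self, params: AcquisitionParams) -> None:
        """The canal disc must lie fully inside the image grid."""
        cx, cy = self.center_mm(params)
        r = self.canal_radius_mm
        if (
            cx - r < 0
            or cy - r < 0
            or cx + r > self.grid_nx * params.voxel_dx
            or cy + r > self.grid_ny * params.voxel_dy
        ):
            raise ValueError(
                f"canal (center ({cx:g}, {cy:g}) mm, radius {r:g} mm) extends "
                f"outside the {self.grid_nx} x {self.grid_ny} grid"
            )


@dataclass
class GroundTruth:
    """Noiseless truth accompanying a simulated series.

    ``waveform_true`` is exactly the mask-summed, area-scaled
    ``velocity_true`` (by construction), and ``metrics_true`` its six metrics.
    """

    velocity_true: np.ndarray
    waveform_true: FlowWaveform
    metrics_true: FlowMetrics
    mask_true: ROIMask
    background_rad: np.ndarray = field(repr=False, default=None)


def encode_velocity(velocity, params: AcquisitionParams) -> np.ndarray:
    """Encode velocity (cm/s) into wrapped phase-contrast phase (rad).

    ``phi = wrap(pi * v / venc)`` with the wrap to [-pi, pi); velocities with
    ``|v| < venc`` round-trip exactly through decoding, ``|v| >= venc``
    alias by multiples of ``2 * venc``.  ``v = +venc`` maps to ``-pi``.
    """
    return wrap_phase(np.pi * np.asarray(velocity, dtype=float) / params.venc)


def canal_mask(spec: PhantomSpec, params: AcquisitionParams) -> ROIMask:
    """Boolean disc mask of the canal lumen (voxel centres within radius)."""
    spec.validate_geometry(params)
    cx, cy = spec.center_mm(params)
    x = (np.arange(spec.grid_nx) + 0.5) * params.voxel_dx
    y = (np.arange(spec.grid_ny) + 0.5) * params.voxel_dy
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    return ROIMask(mask=r2 <= spec.canal_radius_mm**2, voxel_area_mm2=params.voxel_area_mm2)


def _centerline_timecourse(spec: PhantomSpec, params: AcquisitionParams) -> np.ndarray:
    """Centreline velocity (cm/s) at each of the N uniform cardiac phases."""
    k = np.arange(params.n_phases)
    c = np.zeros(params.n_phases)
    for amp, freq, ph in spec.waveform_harmonics:
        c += amp * np.sin(TWO_PI * freq * k / params.n_phases + ph)
    return c


def true_velocity_field(spec: PhantomSpec, params: AcquisitionParams) -> np.ndarray:
    """Noiseless (nx, ny, n_phases) velocity field, cm/s.

    Inside the canal the spatial profile is plug (uniform) or parabolic
    (Poiseuille-like, ``1 - (r/R)^2``, peak at the centreline); outside it is
    exactly zero (static tissue).
    """
    spec.validate_geometry(params)
    cx, cy = spec.center_mm(params)
    x = (np.arange(spec.grid_nx) + 0.5) * params.voxel_dx
    y = (np.arange(spec.grid_ny) + 0.5) * params.voxel_dy
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    inside = r2 <= spec.canal_radius_mm**2
    if spec.velocity_profile == "plug":
        profile = inside.astype(float)
    else:
        profile = np.where(inside, 1.0 - r2 / spec.canal_radius_mm**2, 0.0)
    return profile[:, :, None] * _centerline_timecourse(spec, params)[None, None, :]


def background_plane(spec: PhantomSpec, params: AcquisitionParams) -> np.ndarray:
    """Static background phase (rad): constant offset + linear in-plane ramp."""
    ix = np.arange(spec.grid_nx, dtype=float)
    iy = np.arange(spec.grid_ny, dtype=float)
    rx, ry = spec.background_ramp
    return spec.background_offset_rad + rx * ix[:, None] + ry * iy[None, :]


def generate_phantom(
    spec: PhantomSpec, params: AcquisitionParams | None = None
) -> tuple[MagnitudeSeries, PhaseSeries, GroundTruth]:
    """Simulate one cardiac-gated phase-contrast acquisition.

    Deterministic for a fixed ``spec.seed``.  Phase is
    ``wrap(encode(v_true) + background + noise)``; magnitude is bright inside
    the canal with Rician noise (Gaussian on the two complex channels).
    """
    params = params or AcquisitionParams()
    rng = np.random.default_rng(spec.seed)

    v_true = true_velocity_field(spec, params)
    mask = canal_mask(spec, params)
    bg = background_plane(spec, params)

    phi = np.pi * v_true / params.venc + bg[:, :, None]
    if spec.noise_sd_phase > 0:
        phi = phi + rng.normal(0.0, spec.noise_sd_phase, size=phi.shape)
    phase = PhaseSeries(values=wrap_phase(phi), params=params)

    mag_clean = np.where(mask.mask, MAGNITUDE_CANAL, MAGNITUDE_TISSUE)
    mag = np.broadcast_to(mag_clean[:, :, None], v_true.shape).astype(float)
    if spec.noise_sd_magnitude > 0:
        re = mag + rng.normal(0.0, spec.noise_sd_magnitude, size=mag.shape)
        im = rng.normal(0.0, spec.noise_sd_magnitude, size=mag.shape)
        mag = np.hypot(re, im)
    magnitude = MagnitudeSeries(values=mag, params=params)

    vel_true_series = VelocitySeries(
        values=v_true, params=params, unwrapped=True, background_corrected=True
    )
    waveform_true = compute_waveform(vel_true_series, mask)
    truth = GroundTruth(
        velocity_true=v_true,
        waveform_true=waveform_true,
        metrics_true=compute_metrics(waveform_true),
        mask_true=mask,
        background_rad=bg,
    )
    return magnitude, phase, truth
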