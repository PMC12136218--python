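"""Reconstruction of velocity maps from raw cardiac-gated phase images.

Three explicit stages, in the order they should be applied:

1. :func:`unwrap_temporal` — per-voxel successive-difference unwrapping along
   the cardiac-phase axis.  The flow region is spatially thin but temporally
   smooth, so aliasing (|v| >= venc) shows up as >pi jumps between adjacent
   cardiac phases and can be undone voxel-by-voxel.  The first phase (or a
   configurable anchor) is assumed unaliased.
2. :func:`phase_to_velocity` — the linear decoding ``v = phi * venc / pi``.
3. :func:`correct_background` — fit a low-order polynomial (plane by
   default) to the time-averaged velocity over a static-tissue mask and
   subtract it from every cardiac phase, removing eddy-current-like static
   phase offsets.  :func:`auto_static_mask` derives a static mask from the
   data when none is supplied.
"""

from __future__ import annotations

import warnings

import numpy as np

from .acquisition import wrap_phase
from .series import MagnitudeSeries, PhaseSeries, VelocitySeries

DEFAULT_RANGE_LIMIT = 4.0 * np.pi


class UnreliableUnwrapWarning(UserWarning):
    """Some voxels exceeded the plausible unwrapped phase excursion."""


def phase_to_velocity(phase: PhaseSeries) -> VelocitySeries:
    """Decode phase (rad) to velocity (cm/s): ``v = phi * venc / pi``."""
    return VelocitySeries(
        values=phase.values * (phase.params.venc / np.pi),
        params=phase.params,
        unwrapped=not phase.wrapped,
        unreliable=phase.unreliable,
    )


def unwrap_temporal(
    phase: PhaseSeries,
    anchor: int = 0,
    range_limit: float = DEFAULT_RANGE_LIMIT,
) -> PhaseSeries:
    """Unwrap each voxel's phase time-series along the cardiac-phase axis.

    Wherever the jump between adjacent cardiac phases exceeds pi in
    magnitude, 2*pi is added to or subtracted from the remainder of the
    series.  The sample at ``anchor`` is taken as unaliased and is never
    changed; unwrapping proceeds forward and backward from it.  Output
    values may leave [-pi, pi).  Idempotent on series that are already
    smooth (all |jumps| < pi).

    Voxels whose unwrapped peak-to-peak excursion exceeds ``range_limit``
    (default 4*pi) are flagged in the returned series' ``unreliable`` mask
    and reported via :class:`UnreliableUnwrapWarning`; their values are
    still returned, not silently altered.
    """
    vals = phase.values
    n = vals.shape[2]
    if n < 3:
        raise ValueError(f"temporal unwrapping needs >= 3 cardiac phases, got {n}")
    if not 0 <= anchor < n:
        raise ValueError(f"anchor {anchor} outside [0, {n})")

    d = wrap_phase(np.diff(vals, axis=2))
    out = np.empty_like(vals)
    out[:, :, anchor] = vals[:, :, anchor]
    if anchor < n - 1:
        out[:, :, anchor + 1 :] = (
            vals[:, :, anchor, None] + np.cumsum(d[:, :, anchor:], axis=2)
        )
    if anchor > 0:
        back = np.cumsum(d[:, :, anchor - 1 :: -1], axis=2)
        out[:, :, anchor - 1 :: -1] = vals[:, :, anchor, None] - back

    excursion = out.max(axis=2) - out.min(axis=2)
    unreliable = excursion > range_limit
    if unreliable.any():
        warnings.warn(
            f"{int(unreliable.sum())} voxel(s) exceed the unwrap range limit "
            f"of {range_limit / np.pi:.1f} pi and are flagged unreliable",
            UnreliableUnwrapWarning,
            stacklevel=2,
        )
    return PhaseSeries(
        values=out, params=phase.params, wrapped=False, unreliable=unreliable
    )


def _poly_design(ix: np.ndarray, iy: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(ix, dtype=float)]
    if order >= 1:
        cols += [ix.astype(float), iy.astype(float)]
    if order >= 2:
        cols += [
            ix.astype(float) ** 2,
            iy.astype(float) ** 2,
            ix.astype(float) * iy.astype(float),
        ]
    return np.column_stack(cols)


def fit_background(
    velocity: VelocitySeries, static_mask: np.ndarray, order: int = 1
) -> np.ndarray:
    """Fit the static background velocity surface over ``static_mask``.

    Least-squares fit of an order-0/1/2 polynomial in voxel indices (x, y)
    to the time-averaged velocity of the static voxels; returns the fitted
    surface evaluated over the whole plane (cm/s).
    """
    if order not in (0, 1, 2):
        raise ValueError(f"background order must be 0, 1 or 2, got {order}")
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != velocity.values.shape[:2]:
        raise ValueError("static mask shape does not match the image plane")
    n_static = int(static_mask.sum())
    if n_static < 10:
        raise ValueError(
            f"static mask has {n_static} voxels; >= 10 required for a stable fit"
        )
    ix, iy = np.nonzero(static_mask)
    design = _poly_design(ix, iy, order)
    target = velocity.values.mean(axis=2)[static_mask]
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)

    gx, gy = np.meshgrid(
        np.arange(velocity.values.shape[0]),
        np.arange(velocity.values.shape[1]),
        indexing="ij",
    )
    return (_poly_design(gx.ravel(), gy.ravel(), order) @ coef).reshape(gx.shape)


def correct_background(
    velocity: VelocitySeries, static_mask: np.ndarray, order: int = 1
) -> VelocitySeries:
    """Subtract the fitted static background surface from every cardiac phase.

    After correction the mean velocity over the static mask is zero (to
    numerical precision).  The static mask must not overlap the flow ROI —
    that is the caller's contract, since the ROI is unknown here.
    """
    surface = fit_background(velocity, static_mask, order=order)
    return VelocitySeries(
        values=velocity.values - surface[:, :, None],
        params=velocity.params,
        unwrapped=velocity.unwrapped,
        background_corrected=True,
        unreliable=velocity.unreliable,
    )


def auto_static_mask(
    velocity: VelocitySeries,
    magnitude: MagnitudeSeries | None = None,
    sd_percentile: float = 25.0,
    magnitude_floor_quantile: float = 0.5,
) -> np.ndarray:
    """Derive a static-tissue mask from the data.

    Static voxels are those whose velocity temporal SD falls below the given
    percentile of all voxels' SDs and (when a magnitude series is supplied)
    whose time-averaged magnitude is above the given quantile floor, i.e.
    quiet but signal-bearing tissue.
    """
    sd = velocity.values.std(axis=2)
    mask = sd <= np.percentile(sd, sd_percentile)
    if magnitude is not None:
        mag = magnitude.values.mean(axis=2)
        mask &= mag >= np.quantile(mag, magnitude_floor_quantile)
    return mask


def reconstruct_velocity(
    phase: PhaseSeries,
    magnitude: MagnitudeSeries | None = None,
    unwrap: bool = True,
    anchor: int = 0,
    background_order: int | None = 1,
    static_mask: np.ndarray | None = None,
) -> VelocitySeries:
    """Convenience pipeline: unwrap -> decode -> background-correct.

    ``background_order=None`` skips background correction; otherwise a
    static mask is auto-derived when not supplied.
    """
    if unwrap:
        phase = unwrap_temporal(phase, anchor=anchor)
    velocity = phase_to_velocity(phase)
    if background_order is not None:
        if static_mask is None:
            static_mask = auto_static_mask(velocity, magnitude)
        velocity = correct_background(velocity, static_mask, order=background_order)
    return velocity
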