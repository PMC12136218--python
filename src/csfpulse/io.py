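"""File formats and run configuration.

Cardiac-gated series are stored as 4-D NIfTI (x, y, 1, cardiac_phase) with
the voxel geometry in the header; NIfTI has no native cardiac-phase
semantics, so the cycle duration travels in the pipeline config / JSON
sidecars.  Phase images come in two dialects: floating-point radians in
[-pi, pi), or scanner-style signed integers mapped linearly onto [-pi, pi)
(lo -> -pi, hi + 1 -> +pi, so two's-complement wrap-around is preserved).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .acquisition import AcquisitionParams
from .flow import FlowMetrics, FlowWaveform, ROIMask
from .series import MagnitudeSeries, PhaseSeries

DEFAULT_INT_RANGE = (-4096, 4095)


class GeometryMismatchWarning(UserWarning):
    """NIfTI header geometry disagrees with the configured acquisition."""


def _affine(params: AcquisitionParams) -> np.ndarray:
    return np.diag([params.voxel_dx, params.voxel_dy, params.slice_dz, 1.0])


def save_series(path, values: np.ndarray, params: AcquisitionParams) -> None:
    """Write an (nx, ny, n_phases) series as 4-D NIfTI (x, y, 1, phases)."""
    values = np.asarray(values, dtype=np.float64)
    img = nib.Nifti1Image(values[:, :, None, :], _affine(params))
    img.header.set_zooms(
        (params.voxel_dx, params.voxel_dy, params.slice_dz, params.dt_ms / 1000.0)
    )
    nib.save(img, str(path))


def save_mask(path, mask: np.ndarray, params: AcquisitionParams) -> None:
    """Write a 2-D boolean mask as a 3-D (x, y, 1) NIfTI of 0/1."""
    img = nib.Nifti1Image(
        np.asarray(mask, dtype=np.uint8)[:, :, None], _affine(params)
    )
    nib.save(img, str(path))


def _load_4d(path) -> tuple[np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        if data.shape[2] != 1:
            raise ValueError(
                f"{path}: expected a single slice (x, y, 1, phases), "
                f"got shape {data.shape}"
            )
        data = data[:, :, 0, :]
    elif data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D or 4-D data, got shape {data.shape}")
    return data, img.header.get_zooms()


def _check_geometry(zooms, params: AcquisitionParams, path) -> None:
    header = zooms[:3]
    config = (params.voxel_dx, params.voxel_dy, params.slice_dz)
    if not np.allclose(header, config, rtol=1e-4):
        warnings.warn(
            f"{path}: header voxel geometry {tuple(round(z, 4) for z in header)} "
            f"differs from configured {config}; the configuration wins",
            GeometryMismatchWarning,
            stacklevel=3,
        )


def integer_phase_to_radians(
    values: np.ndarray, int_range: tuple[int, int] = DEFAULT_INT_RANGE
) -> np.ndarray:
    """Map scanner integer phase units linearly onto [-pi, pi)."""
    lo, hi = int_range
    if not lo < hi:
        raise ValueError(f"invalid integer range {int_range}")
    span = hi - lo + 1
    return (np.asarray(values, dtype=np.float64) - lo) * (2.0 * np.pi / span) - np.pi


def read_phase_series(
    path,
    params: AcquisitionParams,
    dialect: str = "radians",
    int_range: tuple[int, int] = DEFAULT_INT_RANGE,
) -> PhaseSeries:
    """Read a phase series, mapping values into [-pi, pi) per dialect."""
    data, zooms = _load_4d(path)
    if data.shape[2] != params.n_phases:
        raise ValueError(
            f"{path}: file has {data.shape[2]} cardiac phases but the "
            f"configuration expects {params.n_phases}"
        )
    _check_geometry(zooms, params, path)
    if dialect == "integer":
        data = integer_phase_to_radians(data, int_range)
    elif dialect != "radians":
        raise ValueError(f"unknown phase dialect {dialect!r}")
    return PhaseSeries(values=data, params=params)


def read_magnitude_series(path, params: AcquisitionParams) -> MagnitudeSeries:
    data, zooms = _load_4d(path)
    if data.shape[2] != params.n_phases:
        raise ValueError(
            f"{path}: file has {data.shape[2]} cardiac phases but the "
            f"configuration expects {params.n_phases}"
        )
    _check_geometry(zooms, params, path)
    return MagnitudeSeries(values=data, params=params)


def read_mask(path, params: AcquisitionParams | None = None) -> np.ndarray:
    """Read a (x, y, 1) or (x, y) NIfTI mask as a 2-D boolean array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    data = np.asarray(nib.load(str(path)).dataobj)
    if data.ndim == 3:
        data = data[:, :, 0]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D mask, got shape {data.shape}")
    return data > 0


def read_roi(path, params: AcquisitionParams) -> ROIMask:
    return ROIMask(mask=read_mask(path), voxel_area_mm2=params.voxel_area_mm2)


# --------------------------------------------------------------------------
# sidecars


def save_velocity_series(path, values: np.ndarray, params: AcquisitionParams) -> None:
    save_series(path, values, params)


def write_truth_sidecar(path, truth, spec, params: AcquisitionParams) -> None:
    """JSON ground-truth sidecar: waveform, metrics, spec echo."""
    payload = {
        "acquisition": dataclasses.asdict(params),
        "phantom_spec": dataclasses.asdict(spec),
        "waveform_mm3_per_s": truth.waveform_true.q.tolist(),
        "dt_ms": truth.waveform_true.dt_ms,
        "metrics": truth.metrics_true.as_dict(),
        "roi_n_voxels": truth.mask_true.n_voxels,
        "roi_area_mm2": truth.mask_true.area_mm2,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_metrics_json(path, waveform: FlowWaveform, metrics: FlowMetrics) -> None:
    payload = {
        "metrics": metrics.as_dict(),
        "waveform_mm3_per_s": waveform.q.tolist(),
        "dt_ms": waveform.dt_ms,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through YAML.

    Defaults mirror the documented spinal-canal protocol (VENC 10 cm/s, 40
    phases, 453 ms cycle) and the analysis conventions (Spearman, p < 0.05).
    """

    acquisition: AcquisitionParams = AcquisitionParams()
    phase_dialect: str = "radians"
    int_range: tuple[int, int] = DEFAULT_INT_RANGE
    unwrap: bool = True
    unwrap_anchor: int = 0
    background_order: int | None = 1
    metric_units: str = "phase_sum"  # or "mm3"
    association_method: str = "spearman"
    alpha: float = 0.05
    seed: int = 0
    n_subjects: int = 16

    def __post_init__(self) -> None:
        if self.phase_dialect not in ("radians", "integer"):
            raise ValueError(f"unknown phase dialect {self.phase_dialect!r}")
        if self.background_order not in (None, 0, 1, 2):
            raise ValueError("background_order must be None, 0, 1 or 2")
        if self.metric_units not in ("phase_sum", "mm3"):
            raise ValueError("metric_units must be 'phase_sum' or 'mm3'")
        if self.association_method not in ("spearman", "pearson"):
            raise ValueError("association_method must be 'spearman' or 'pearson'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["int_range"] = list(self.int_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            d["acquisition"] = AcquisitionParams(**d["acquisition"])
        if "int_range" in d:
            d["int_range"] = tuple(d["int_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
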