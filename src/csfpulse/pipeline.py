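"""End-to-end orchestration: simulate/ingest -> reconstruct -> metrics ->
cohort -> association, with a reproducibility manifest.

Every run emits a ``manifest.json`` recording the configuration echo, input
checksums, software version, per-stage timings and warnings; reruns with the
same configuration and seed produce identical analytic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as csfio
from .assoc import run_association_report
from .cohort import METRIC_COLUMNS, CohortSpec, generate_cohort
from .flow import compute_metrics, compute_waveform
from .io import PipelineConfig
from .phantom import PhantomSpec, generate_phantom
from .recon import reconstruct_velocity


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the input."""


@dataclass
class RunManifest:
    config: dict
    version: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    metrics: dict | None = None

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.timings_s[name] = round(time.perf_counter() - self.t0, 6)
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Timer()


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    simulate: bool = True,
    phantom_spec: PhantomSpec | None = None,
    cohort_spec: CohortSpec | None = None,
    phase_path=None,
    magnitude_path=None,
    roi_path=None,
    static_mask_path=None,
    cohort_path=None,
) -> RunManifest:
    """Run the full analysis; returns (and writes) the run manifest.

    With ``simulate=True`` the phantom module sources the image series, ROI
    and cohort table; otherwise the file paths must point at existing NIfTI
    series / masks and (optionally) a cohort CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.acquisition
    manifest = RunManifest(config=config.to_dict(), version=__version__)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with _stage(manifest, "ingest"):
            if simulate:
                spec = phantom_spec or PhantomSpec(seed=config.seed)
                magnitude, phase, truth = generate_phantom(spec, params)
                roi = truth.mask_true
                csfio.save_series(out / "magnitude.nii.gz", magnitude.values, params)
                csfio.save_series(out / "phase.nii.gz", phase.values, params)
                csfio.save_mask(out / "roi.nii.gz", roi.mask, params)
                csfio.write_truth_sidecar(out / "truth.json", truth, spec, params)
                static_mask = None
            else:
                for label, p in (("phase", phase_path), ("roi", roi_path)):
                    if p is None or not Path(p).exists():
                        raise FileNotFoundError(f"{label} input not found: {p}")
                phase = csfio.read_phase_series(
                    phase_path, params, config.phase_dialect, config.int_range
                )
                magnitude = (
                    csfio.read_magnitude_series(magnitude_path, params)
                    if magnitude_path
                    else None
                )
                roi = csfio.read_roi(roi_path, params)
                static_mask = (
                    csfio.read_mask(static_mask_path) if static_mask_path else None
                )
                for label, p in (
                    ("phase", phase_path),
                    ("magnitude", magnitude_path),
                    ("roi", roi_path),
                    ("static_mask", static_mask_path),
                ):
                    if p:
                        manifest.inputs[label] = file_checksum(p)

        with _stage(manifest, "reconstruct"):
            velocity = reconstruct_velocity(
                phase,
                magnitude,
                unwrap=config.unwrap,
                anchor=config.unwrap_anchor,
                background_order=config.background_order,
                static_mask=static_mask,
            )
            csfio.save_velocity_series(out / "velocity.nii.gz", velocity.values, params)

        with _stage(manifest, "metrics"):
            waveform = compute_waveform(velocity, roi)
            metrics = compute_metrics(waveform)
            csfio.write_metrics_json(out / "metrics.json", waveform, metrics)
            manifest.metrics = metrics.as_dict()

        with _stage(manifest, "cohort"):
            if cohort_path is not None:
                if not Path(cohort_path).exists():
                    raise FileNotFoundError(f"cohort table not found: {cohort_path}")
                cohort = pd.read_csv(cohort_path)
                manifest.inputs["cohort"] = file_checksum(cohort_path)
            else:
                cohort = generate_cohort(cohort_spec or CohortSpec(
                    n_subjects=config.n_subjects, seed=config.seed
                ))
            cohort.to_csv(out / "cohort.csv", index=False, float_format="%.10g")

        with _stage(manifest, "associate"):
            report = run_association_report(
                cohort,
                metrics=[c for c in METRIC_COLUMNS if c in cohort.columns],
                method=config.association_method,
                alpha=config.alpha,
            )
            report.write(out / "association")

        manifest.warnings = [str(w.message) for w in caught]

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.outputs[str(f.relative_to(out))] = file_checksum(f)
    manifest.write(out / "manifest.json")
    return manifest
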