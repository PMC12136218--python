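"""End-to-end validation experiments on synthetic data.

Each function runs one self-contained experiment — round-trip precision,
noiseless phantom recovery, statistical route equivalences, type-I error
calibration, cohort parameter recovery, noise-bias characterisation — and
returns the measured quantities.  They are used both by the acceptance test
suite and by ``scripts/acceptance.py``; all randomness is seed-controlled.
"""

from __future__ import annotations

import numpy as np

from .acquisition import AcquisitionParams
from .assoc import (
    _ols_residuals,
    _pearson,
    _ranks,
    correlate,
    partial_correlation_arrays,
    residualization_arrays,
)
from .cohort import METRIC_DIRECTIONS, CohortSpec, generate_cohort
from .flow import compute_metrics, compute_waveform
from .phantom import PhantomSpec, encode_velocity, generate_phantom
from .recon import reconstruct_velocity

# Two-harmonic test waveforms (DC mean-flow term + two harmonics,
# centreline cm/s).  The DC keeps every metric, net stroke included, well
# away from zero so relative errors are meaningful.  The aliased variant
# peaks at ~1.6 x VENC with v(phase 0) = 0.8 cm/s, so the unwrap anchor
# (phase 0) is unaliased.
CLEAN_HARMONICS = ((0.6, 0.0, np.pi / 2), (3.0, 1.0, 0.8), (1.2, 2.0, 2.0))
ALIASED_HARMONICS = ((0.8, 0.0, np.pi / 2), (13.6, 1.0, 0.0), (4.0, 2.0, 0.0))


def velocity_roundtrip_max_error(
    n: int = 100_000, seed: int = 0, params: AcquisitionParams | None = None
) -> float:
    """Max |decode(encode(v)) - v| (cm/s) over random velocities |v| < venc."""
    params = params or AcquisitionParams()
    rng = np.random.default_rng(seed)
    v = rng.uniform(-params.venc, params.venc, size=n)
    v = v[np.abs(v) < params.venc]
    decoded = encode_velocity(v, params) * params.venc / np.pi
    return float(np.abs(decoded - v).max())


def _border_static_mask(spec: PhantomSpec, width: int = 8) -> np.ndarray:
    mask = np.zeros((spec.grid_nx, spec.grid_ny), dtype=bool)
    mask[:width, :] = mask[-width:, :] = True
    mask[:, :width] = mask[:, -width:] = True
    return mask


def _phantom_recovery_max_rel_error(
    spec: PhantomSpec, params: AcquisitionParams
) -> float:
    _, phase, truth = generate_phantom(spec, params)
    vel = reconstruct_velocity(
        phase, unwrap=True, background_order=1,
        static_mask=_border_static_mask(spec),
    )
    metrics = compute_metrics(compute_waveform(vel, truth.mask_true))
    est = metrics.values()
    ref = truth.metrics_true.values()
    return float(np.max(np.abs(est - ref) / np.abs(ref)))


def noiseless_phantom_recovery(
    params: AcquisitionParams | None = None,
) -> dict[str, float]:
    """Recovery of ground-truth metrics through the full reconstruction.

    ``clean``: a two-harmonic 64 x 64, 40-phase phantom with no corruption.
    ``aliased``: peak velocity 1.5 x venc plus a static background plane
    (0.3 rad offset, in-plane ramps), recovered via temporal unwrapping and
    plane subtraction.  Values are max relative errors over the six metrics.
    """
    params = params or AcquisitionParams()
    clean = PhantomSpec(waveform_harmonics=CLEAN_HARMONICS)
    aliased = PhantomSpec(
        waveform_harmonics=ALIASED_HARMONICS,
        background_offset_rad=0.3,
        background_ramp=(0.004, -0.003),
    )
    _, _, truth = generate_phantom(aliased, params)
    assert np.abs(truth.velocity_true).max() > params.venc
    return {
        "clean_max_rel_error": _phantom_recovery_max_rel_error(clean, params),
        "aliased_max_rel_error": _phantom_recovery_max_rel_error(aliased, params),
    }


def metric_identity_max_violation(
    n_waveforms: int = 1000, n_phases: int = 40, seed: int = 0
) -> float:
    """Max scaled violation of the metric identities over random waveforms.

    Checks net = cranial - caudal, absolute = cranial + caudal,
    |net| <= absolute, amplitude <= 2 peak, peak <= amplitude (for
    zero-spanning waveforms) and degree-1 homogeneity under scaling.
    """
    from .flow import FlowWaveform

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_waveforms):
        q = rng.normal(0.0, rng.uniform(0.5, 50.0), size=n_phases)
        w = FlowWaveform(q=q, dt_ms=453.0 / n_phases)
        m = compute_metrics(w)
        scale = max(1.0, m.absolute_stroke)
        viol = [
            abs(m.net_stroke - (m.cranial_volume - m.caudal_volume)),
            abs(m.absolute_stroke - (m.cranial_volume + m.caudal_volume)),
            max(0.0, abs(m.net_stroke) - m.absolute_stroke),
            max(0.0, m.amplitude - 2.0 * m.peak),
        ]
        if q.min() <= 0.0 <= q.max():
            viol.append(max(0.0, m.peak - m.amplitude))
        alpha = float(rng.uniform(0.1, 10.0))
        ms = compute_metrics(FlowWaveform(q=alpha * q, dt_ms=w.dt_ms))
        viol.append(float(np.max(np.abs(ms.values() - alpha * m.values()))))
        worst = max(worst, max(viol) / scale)
    return worst


def partial_correlation_route_max_diff(
    n_tables: int = 100, n: int = 16, seed: int = 0, method: str = "pearson"
) -> float:
    """Max |closed-form - residual-route| partial correlation over random
    Gaussian triples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        x, y, z = rng.normal(size=(3, n))
        if method == "spearman":
            x, y, z = _ranks(x), _ranks(y), _ranks(z)
        r_xy, r_xz, r_yz = _pearson(x, y), _pearson(x, z), _pearson(y, z)
        closed = (r_xy - r_xz * r_yz) / np.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2)
        )
        design = np.column_stack([np.ones(n), z])
        resid = _pearson(_ols_residuals(x, design), _ols_residuals(y, design))
        worst = max(worst, abs(closed - resid))
    return worst


def twin_t_statistic_max_diff(
    n_tables: int = 100, n: int = 16, seed: int = 0
) -> float:
    """Max |residualization t - Pearson partial-correlation t| over random
    complete tables (the twin-column identity)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        x, y, z = rng.normal(size=(3, n))
        _, _, t, _, _ = residualization_arrays(x, y, z)
        r, _, df = partial_correlation_arrays(x, y, z, method="pearson")
        t_pc = r * np.sqrt(df / (1.0 - r**2))
        worst = max(worst, abs(t - t_pc))
    return worst


def type_i_error_rate(
    n_reps: int = 5000, n: int = 16, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the Pearson partial-correlation test under a
    Gaussian null (x, y, z independent)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x, y, z = rng.normal(size=(3, n))
        _, p, _ = partial_correlation_arrays(x, y, z, method="pearson")
        rejections += p < alpha
    return rejections / n_reps


def cohort_parameter_recovery(seed: int = 0, n_large: int = 5000) -> dict[str, float]:
    """Monte-Carlo recovery of the cohort generator's population targets."""
    table = generate_cohort(CohortSpec(n_subjects=n_large, seed=seed))
    rho_age_flow, _, _ = correlate(
        table["age_years"].to_numpy(), table["peak"].to_numpy(), method="spearman"
    )
    rho_partial, _, _ = partial_correlation_arrays(
        table["peak"].to_numpy(),
        table["csf_ab42_40_ratio"].to_numpy(),
        table["age_years"].to_numpy(),
        method="spearman",
    )
    return {
        "rho_age_flow": float(rho_age_flow),
        "rho_flow_ratio_partial": float(rho_partial),
    }


def sign_pattern_recovery(
    n_reps: int = 500, n_subjects: int = 16, alpha: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Small-sample recovery of the qualitative association pattern.

    For each simulated 16-subject cohort: the age-metric correlation must
    carry the metric's expected sign (negative for flow-increasing metrics),
    the metric-Abeta42/40-ratio correlation the opposite pattern, and each
    plasma (null) biomarker cell must be non-significant.  Returns the
    minimum per-cell recovery fractions over the replicates.
    """
    plasma = ("plasma_ab42_40_ratio", "plasma_ptau181", "plasma_nfl", "plasma_gfap")
    metrics = list(METRIC_DIRECTIONS)
    age_sign_hits = {m: 0 for m in metrics}
    ratio_sign_hits = {m: 0 for m in metrics}
    plasma_ns_hits = {(m, b): 0 for m in metrics for b in plasma}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        table = generate_cohort(
            CohortSpec(n_subjects=n_subjects, seed=int(rng.integers(2**31)))
        )
        age = table["age_years"].to_numpy()
        ratio = table["csf_ab42_40_ratio"].to_numpy()
        for m in metrics:
            col = table[m].to_numpy()
            direction = METRIC_DIRECTIONS[m]
            r_age, _, _ = correlate(age, col, method="spearman")
            age_sign_hits[m] += np.sign(r_age) == -direction
            r_ratio, _, _ = correlate(col, ratio, method="spearman")
            ratio_sign_hits[m] += np.sign(r_ratio) == direction
            for b in plasma:
                _, p, _ = correlate(col, table[b].to_numpy(), method="spearman")
                plasma_ns_hits[(m, b)] += p >= alpha
    return {
        "min_age_sign_fraction": min(age_sign_hits.values()) / n_reps,
        "min_ratio_sign_fraction": min(ratio_sign_hits.values()) / n_reps,
        "min_plasma_nonsig_fraction": min(plasma_ns_hits.values()) / n_reps,
    }


def phase_noise_sd_for_waveform_snr(
    spec: PhantomSpec, params: AcquisitionParams, snr: float
) -> float:
    """Phase-noise SD (rad) giving the requested ROI-waveform SNR.

    Independent per-voxel velocity noise of SD sigma_v sums over the N-voxel
    ROI into flow-rate noise of SD sqrt(N) * sigma_v * 10 * area; SNR is
    defined as peak |q_true| over that SD.
    """
    _, _, truth = generate_phantom(spec, params)
    peak_q = float(np.abs(truth.waveform_true.q).max())
    n_vox = truth.mask_true.n_voxels
    sigma_v = peak_q / (
        snr * np.sqrt(n_vox) * 10.0 * params.voxel_area_mm2
    )
    return sigma_v * np.pi / params.venc


def noise_bias_characterisation(
    n_seeds: int = 100, snr: float = 5.0, seed: int = 0
) -> dict[str, float]:
    """Bias/variance of stroke-volume estimates at a given waveform SNR.

    Rectified noise biases the absolute stroke volume upward, while the net
    stroke volume stays unbiased but with a large standard deviation — the
    reason small-cohort net-stroke measurements are unreliable.
    """
    params = AcquisitionParams()
    base = PhantomSpec()
    sigma_phi = phase_noise_sd_for_waveform_snr(base, params, snr)
    _, _, truth = generate_phantom(base, params)

    abs_est, net_est = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_seeds):
        spec = PhantomSpec(
            noise_sd_phase=sigma_phi, seed=int(rng.integers(2**31))
        )
        _, phase, _ = generate_phantom(spec, params)
        vel = reconstruct_velocity(phase, unwrap=True, background_order=None)
        m = compute_metrics(compute_waveform(vel, truth.mask_true))
        abs_est.append(m.absolute_stroke)
        net_est.append(m.net_stroke)
    abs_est = np.asarray(abs_est)
    net_est = np.asarray(net_est)
    return {
        "snr": snr,
        "phase_noise_sd_rad": float(sigma_phi),
        "absolute_stroke_true": truth.metrics_true.absolute_stroke,
        "absolute_stroke_mean": float(abs_est.mean()),
        "absolute_stroke_bias": float(abs_est.mean())
        - truth.metrics_true.absolute_stroke,
        "absolute_stroke_sem": float(abs_est.std(ddof=1) / np.sqrt(n_seeds)),
        "net_stroke_true": truth.metrics_true.net_stroke,
        "net_stroke_mean": float(net_est.mean()),
        "net_stroke_bias": float(net_est.mean()) - truth.metrics_true.net_stroke,
        "net_stroke_sd": float(net_est.std(ddof=1)),
        "net_stroke_sem": float(net_est.std(ddof=1) / np.sqrt(n_seeds)),
    }
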