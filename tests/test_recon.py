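import numpy as np
import pytest

from csfpulse import (
    AcquisitionParams,
    PhantomSpec,
    PhaseSeries,
    VelocitySeries,
    auto_static_mask,
    correct_background,
    generate_phantom,
    phase_to_velocity,
    reconstruct_velocity,
    unwrap_temporal,
)
from csfpulse.recon import UnreliableUnwrapWarning, fit_background


def phase_series(values, params):
    return PhaseSeries(values=np.asarray(values, dtype=float), params=params)


class TestPhaseToVelocity:
    @pytest.mark.parametrize(
        "phi,expected",
        [(np.pi / 2, 5.0), (0.0, 0.0), (-np.pi / 2, -5.0)],
    )
    def test_decoding_formula(self, small_params, phi, expected):
        vals = np.full((2, 2, small_params.n_phases), phi)
        vel = phase_to_velocity(phase_series(vals, small_params))
        assert np.allclose(vel.values, expected)

    def test_linearity_in_phase(self, small_params, rng):
        vals = rng.uniform(-1.0, 1.0, size=(4, 4, small_params.n_phases))
        v1 = phase_to_velocity(phase_series(vals, small_params)).values
        v2 = phase_to_velocity(phase_series(0.5 * vals, small_params)).values
        assert np.allclose(v2, 0.5 * v1, atol=1e-14)


class TestUnwrapTemporal:
    def test_hand_unwrapped_series(self):
        # [0.9pi, -0.9pi, 0.9pi]: the -1.8pi jump wraps to +0.2pi, so the
        # series continues upward through 1.1pi and back
        params = AcquisitionParams(n_phases=3)
        vals = np.array([[[0.9 * np.pi, -0.9 * np.pi, 0.9 * np.pi]]])
        out = unwrap_temporal(phase_series(vals, params))
        assert np.allclose(
            out.values[0, 0], [0.9 * np.pi, 1.1 * np.pi, 0.9 * np.pi], atol=1e-12
        )
        assert not out.wrapped

    def test_smooth_series_unchanged(self, small_params, rng):
        # cumulative small steps never exceed |pi| between phases
        steps = rng.uniform(-0.3, 0.3, size=(3, 3, small_params.n_phases))
        vals = np.clip(np.cumsum(steps, axis=2), -3.0, 3.0)
        vals = np.clip(vals, -np.pi, np.pi - 1e-9)
        out = unwrap_temporal(phase_series(vals, small_params))
        assert np.allclose(out.values, vals, atol=1e-12)

    def test_only_multiples_of_two_pi_added(self, small_params, rng):
        vals = rng.uniform(-np.pi, np.pi - 1e-9, size=(5, 5, small_params.n_phases))
        out = unwrap_temporal(phase_series(vals, small_params))
        shifts = (out.values - vals) / (2 * np.pi)
        assert np.allclose(shifts, np.round(shifts), atol=1e-9)

    def test_anchor_sample_never_changed(self, small_params, rng):
        vals = rng.uniform(-np.pi, np.pi - 1e-9, size=(4, 4, small_params.n_phases))
        for anchor in (0, 3, small_params.n_phases - 1):
            out = unwrap_temporal(phase_series(vals, small_params), anchor=anchor)
            assert np.array_equal(out.values[:, :, anchor], vals[:, :, anchor])

    def test_aliased_phantom_recovered(self, params):
        # peak true velocity 1.5 x venc; phase 0 is unaliased (sin(0) = 0)
        spec = PhantomSpec(
            waveform_harmonics=((13.6, 1.0, 0.0), (4.0, 2.0, 0.0)),
        )
        _, phase, truth = generate_phantom(spec, params)
        assert np.abs(truth.velocity_true).max() > params.venc  # really aliased
        vel = phase_to_velocity(unwrap_temporal(phase))
        assert np.allclose(vel.values, truth.velocity_true, atol=1e-9)

    def test_excessive_range_flagged_not_corrected(self):
        params = AcquisitionParams(n_phases=12)
        # a voxel spiralling upward by 0.9 pi per phase: range > 4 pi
        ramp = np.arange(12) * 0.9 * np.pi
        from csfpulse import wrap_phase

        vals = np.zeros((2, 1, 12))
        vals[0, 0] = wrap_phase(ramp)
        with pytest.warns(UnreliableUnwrapWarning):
            out = unwrap_temporal(phase_series(vals, params))
        assert out.unreliable[0, 0]
        assert not out.unreliable[1, 0]
        assert np.allclose(out.values[0, 0], ramp, atol=1e-12)  # still returned

    def test_too_few_phases_rejected(self):
        params = AcquisitionParams(n_phases=2)
        with pytest.raises(ValueError, match=">= 3"):
            unwrap_temporal(phase_series(np.zeros((2, 2, 2)), params))


class TestBackgroundCorrection:
    def _velocity(self, values, params):
        return VelocitySeries(values=values, params=params, unwrapped=True)

    def test_recovers_injected_constant_offset(self, params):
        offset_rad = 0.25
        spec = PhantomSpec(background_offset_rad=offset_rad)
        _, phase, truth = generate_phantom(spec, params)
        vel = phase_to_velocity(phase)
        static = ~truth.mask_true.mask
        fitted = fit_background(vel, static, order=1)
        assert np.allclose(
            fitted, offset_rad * params.venc / np.pi, atol=1e-9
        )
        corrected = correct_background(vel, static)
        assert np.allclose(corrected.values, truth.velocity_true, atol=1e-9)

    def test_identity_on_clean_data(self, params):
        _, phase, truth = generate_phantom(PhantomSpec(), params)
        vel = phase_to_velocity(phase)
        corrected = correct_background(vel, ~truth.mask_true.mask)
        assert np.allclose(corrected.values, vel.values, atol=1e-12)

    def test_static_mean_zero_after_correction(self, params, rng):
        vals = rng.normal(0, 0.3, size=(16, 16, params.n_phases))
        vel = self._velocity(vals, params)
        static = np.ones((16, 16), dtype=bool)
        corrected = correct_background(vel, static, order=1)
        assert abs(corrected.values.mean(axis=2)[static].mean()) < 1e-10

    def test_ramp_removed_below_noise_floor(self, params):
        noise_sd_phase = 0.05
        spec = PhantomSpec(
            background_ramp=(0.01, -0.008),
            noise_sd_phase=noise_sd_phase,
            seed=3,
        )
        _, phase, truth = generate_phantom(spec, params)
        vel = phase_to_velocity(phase)
        corrected = correct_background(vel, ~truth.mask_true.mask)
        static_resid = corrected.values.mean(axis=2)[~truth.mask_true.mask]
        noise_sd_velocity = noise_sd_phase * params.venc / np.pi
        # time-averaged residual SD is sqrt(N) below single-frame noise
        assert static_resid.std() < noise_sd_velocity

    def test_small_static_mask_rejected(self, params):
        vel = self._velocity(np.zeros((8, 8, params.n_phases)), params)
        mask = np.zeros((8, 8), dtype=bool)
        mask[:3, 0] = True
        with pytest.raises(ValueError, match=">= 10"):
            correct_background(vel, mask)


class TestAutoStaticMask:
    def test_excludes_pulsatile_canal(self, params):
        mag, phase, truth = generate_phantom(
            PhantomSpec(noise_sd_phase=0.01, seed=1), params
        )
        vel = phase_to_velocity(phase)
        static = auto_static_mask(vel, mag, magnitude_floor_quantile=0.0)
        # the genuinely pulsatile canal core must be excluded (rim voxels
        # with near-zero parabolic-profile velocity are legitimately quiet)
        core = np.abs(truth.velocity_true).max(axis=2) > 0.05
        assert core.any()
        assert not (static & core).any()
        assert static.sum() >= 10


class TestReconstructVelocity:
    def test_full_pipeline_matches_truth(self, params):
        spec = PhantomSpec(
            background_offset_rad=0.2, background_ramp=(0.002, -0.001)
        )
        _, phase, truth = generate_phantom(spec, params)
        vel = reconstruct_velocity(
            phase, static_mask=~truth.mask_true.mask
        )
        assert vel.background_corrected
        assert np.allclose(vel.values, truth.velocity_true, atol=1e-9)
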