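"""Hologram forward model, Fourier-sideband reconstruction, and the phase
noise budget."""

import math

import numpy as np
import pytest

import mipqpi.holography as H
from mipqpi.core import PhaseMap
from mipqpi.holography import (
    SENSOR_2M,
    SENSOR_10K,
    OffAxisConfig,
    SensorModel,
    aperture_pixels,
    electrons_from_counts,
    infer_visibility,
    measure_temporal_noise,
    predict_phase_noise,
    reconstruct_phase,
    synthesize_hologram,
)
from mipqpi.synth import make_hologram_stack

N = 128
SMALL = SensorModel("small", full_well=2e6, bit_depth=11, gain=1.0,
                    read_noise=0.0, frame_shape=(N, N))


def small_config(v=0.8, diameter=40):
    return OffAxisConfig(carrier=(0.25, 0.25), aperture_diameter=diameter,
                         visibility=v, frame_shape=(N, N))


def mc_noise(v, n_electron, read_noise, n_frames=40, diameter=40, seed=7):
    """Monte-Carlo phase noise of the synth→reconstruct pipeline (mrad)."""
    cfg = small_config(v, diameter)
    sens = SensorModel("mc", 4e6, 11, 1.0, read_noise, (N, N))
    stack = make_hologram_stack(np.zeros((N, N)), sens, cfg, n_electron,
                                n_frames, seed=seed)
    phases = np.stack([reconstruct_phase(f, cfg).values for f in stack])
    return measure_temporal_noise(phases, roi=(24, 24, 80, 80), estimator="rms")


def predicted(v, n_electron, read_noise, diameter=40):
    cfg = small_config(v, diameter)
    mask, _ = H.sideband_mask((N, N), cfg)
    sens = SensorModel("mc", 4e6, 11, 1.0, read_noise, (N, N))
    return predict_phase_noise(n_electron, sens, cfg,
                               aperture_area=int(mask.sum()), sensor_area=N * N)


class TestApertureBookkeeping:
    def test_printed_pixel_counts(self):
        assert aperture_pixels(245) == 47144
        assert aperture_pixels(201) == 31731

    def test_sensor_pixel_counts(self):
        assert SENSOR_2M.n_pixels == 2_073_600
        assert SENSOR_10K.n_pixels == 1_046_529


class TestNoiseModel:
    def test_shot_limit_inverse_sqrt_scaling(self):
        cfg = OffAxisConfig(carrier=(0.25, 0.25), aperture_diameter=245, visibility=0.8)
        s0 = SensorModel("ideal", 2e6, 11, 1.0, 0.0, (1440, 1440))
        assert predict_phase_noise(4e5, s0, cfg) == pytest.approx(
            predict_phase_noise(1e5, s0, cfg) / 2.0
        )

    def test_measured_operating_points(self):
        """Visibility inverted from the 0.9-mrad point predicts ~0.4 mrad in
        the shot limit at N = 10⁶ e⁻."""
        v = infer_visibility(0.9, 3.6e5, SENSOR_2M, aperture_area=47144)
        assert v == pytest.approx(0.772, abs=0.005)
        cfg = OffAxisConfig(carrier=(0.25, 0.25), aperture_diameter=245, visibility=v)
        shot = predict_phase_noise(1e6, SENSOR_2M, cfg, read_noise=0.0)
        assert 0.35 <= shot <= 0.45

    def test_visibility_round_trip(self):
        cfg = OffAxisConfig(carrier=(0.25, 0.25), aperture_diameter=245, visibility=0.63)
        sigma = predict_phase_noise(2e5, SENSOR_2M, cfg)
        v = infer_visibility(sigma, 2e5, SENSOR_2M, aperture_area=cfg.aperture_area)
        assert v == pytest.approx(0.63, abs=1e-12)

    def test_noise_below_unit_visibility_floor_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            infer_visibility(1e-6, 3.6e5, SENSOR_2M)

    def test_zero_visibility_rejected(self):
        with pytest.raises(ValueError):
            OffAxisConfig(carrier=(0.25, 0.25), aperture_diameter=245, visibility=0.0)


class TestElectronConversion:
    def test_zero_and_negative(self):
        assert electrons_from_counts(0.0, SENSOR_2M) == 0.0
        with pytest.raises(ValueError):
            electrons_from_counts(-1.0, SENSOR_2M)

    def test_half_scale_conversion(self):
        # documented formula: value × full_well / ((2^bits − 1) gain)
        value = (2**11 - 1) / 2
        expected = value * 2e6 / ((2**11 - 1) * 1.73)
        assert electrons_from_counts(value, SENSOR_2M) == pytest.approx(expected)

    def test_saturation_warns(self):
        with pytest.warns(UserWarning, match="saturated"):
            electrons_from_counts(2**11 - 1, SENSOR_2M)


class TestForwardModel:
    def test_zero_visibility_no_noise_is_flat(self):
        cfg = OffAxisConfig(carrier=(0.25, 0.25), aperture_diameter=40,
                            visibility=1e-12, frame_shape=(N, N))
        holo = synthesize_hologram(np.zeros((N, N)), cfg, 1e5, SMALL,
                                   shot_noise=False, quantize=False)
        assert np.allclose(holo, 1e5, rtol=1e-9)

    def test_fringe_contrast_equals_visibility(self):
        cfg = small_config(v=0.7)
        holo = synthesize_hologram(np.zeros((N, N)), cfg, 1e5, SMALL,
                                   shot_noise=False, quantize=False)
        contrast = (holo.max() - holo.min()) / (holo.max() + holo.min())
        assert contrast == pytest.approx(0.7, abs=1e-6)

    def test_pixel_variance_is_poisson_plus_read(self):
        sens = SensorModel("rn", 4e6, 11, 1.0, 30.0, (8, 8))
        cfg = OffAxisConfig(carrier=(0.25, 0.25), aperture_diameter=2,
                            visibility=1e-9, frame_shape=(8, 8))
        rng = np.random.default_rng(5)
        frames = np.stack([
            synthesize_hologram(np.zeros((8, 8)), cfg, 2e3, sens, rng=rng, quantize=False)
            for _ in range(10_000)
        ])
        var = frames.var(axis=0).mean()
        assert var == pytest.approx(2e3 + 30.0**2, rel=0.03)

    def test_full_well_clipping_warns(self):
        with pytest.warns(UserWarning, match="full well"):
            synthesize_hologram(np.zeros((N, N)), small_config(), 1.9e6, SMALL,
                                shot_noise=False)

    def test_reproducible_under_seed(self):
        a = synthesize_hologram(np.zeros((N, N)), small_config(), 1e4, SMALL, rng=42)
        b = synthesize_hologram(np.zeros((N, N)), small_config(), 1e4, SMALL, rng=42)
        assert np.array_equal(a, b)


class TestReconstruction:
    def test_flat_phase_gives_constant_map(self):
        holo = synthesize_hologram(np.zeros((N, N)), small_config(), 1e5, SMALL,
                                   shot_noise=False, quantize=False)
        phase = reconstruct_phase(holo, small_config()).values
        assert phase.std() < 1e-6 * 1e3  # < 1e-6 rad, in mrad

    def test_gaussian_bump_round_trip(self):
        """0.5-rad bump, σ = 10 px: forward–inverse RMS error < 1e-3 rad."""
        yy, xx = np.mgrid[0:N, 0:N]
        bump = 0.5 * np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 10.0**2))
        cfg = small_config()
        ref = reconstruct_phase(
            synthesize_hologram(np.zeros((N, N)), cfg, 1e5, SMALL, shot_noise=False,
                                quantize=False), cfg).values
        rec = reconstruct_phase(
            synthesize_hologram(bump, cfg, 1e5, SMALL, shot_noise=False,
                                quantize=False), cfg).values
        err = (rec - ref) * 1e-3 - bump
        assert math.sqrt(float((err**2).mean())) < 1e-3

    def test_missing_carrier_rejected(self):
        rng = np.random.default_rng(0)
        noise_only = rng.normal(1000.0, 1.0, size=(N, N))
        cfg = small_config(diameter=10)
        with pytest.raises(ValueError, match="carrier"):
            reconstruct_phase(noise_only, cfg)

    def test_detect_carrier_finds_configured_one(self):
        holo = synthesize_hologram(np.zeros((N, N)), small_config(), 1e5, SMALL,
                                   shot_noise=False, quantize=False)
        fy, fx = H.detect_carrier(holo)
        assert (abs(fy), abs(fx)) == (pytest.approx(0.25, abs=0.01),) * 2


class TestTemporalNoise:
    def test_iid_gaussian_gives_sqrt2_sigma(self, rng):
        stack = rng.normal(0.0, 3.0, size=(51, 100, 100))
        got = measure_temporal_noise(stack, roi=(10, 10, 80, 80))
        assert got == pytest.approx(3.0 * math.sqrt(2), rel=0.03)

    def test_identical_frames_give_zero(self):
        stack = np.tile(np.arange(100.0).reshape(10, 10), (5, 1, 1))
        assert measure_temporal_noise(stack, roi=(0, 0, 10, 10)) == 0.0

    def test_roi_outside_rejected(self, rng):
        stack = rng.normal(size=(5, 32, 32))
        with pytest.raises(ValueError, match="roi"):
            measure_temporal_noise(stack, roi=(0, 0, 80, 80))

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="3 frames"):
            measure_temporal_noise(rng.normal(size=(2, 32, 32)), roi=(0, 0, 32, 32))


class TestMonteCarloBudget:
    def test_pipeline_matches_model_at_reference_point(self):
        got = mc_noise(0.8, 1e5, 0.0)
        assert got == pytest.approx(predicted(0.8, 1e5, 0.0), rel=0.10)

    def test_spatial_averaging_scales_with_aperture_area(self):
        """σ ∝ √A_aperture at fixed sensor area."""
        big = mc_noise(0.8, 1e4, 0.0, diameter=40, seed=3)
        small = mc_noise(0.8, 1e4, 0.0, diameter=20, seed=4)
        assert big / small == pytest.approx(
            predicted(0.8, 1e4, 0.0, 40) / predicted(0.8, 1e4, 0.0, 20), rel=0.10
        )
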