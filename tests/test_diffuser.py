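"""Diffuser surfaces, phase screens, motion schedules and decorrelation."""

import warnings

import numpy as np
import pytest
from scipy import stats

from smoct import (
    BeamSpec,
    DiffuserSurface,
    ScreenSampler,
    generate_surface,
    min_span_for_full_phase,
    motion_schedule,
    phase_screen,
    screen_decorrelation,
    surface_from_preset,
)


class TestSurfaceGeneration:
    def test_flat_surface(self):
        s = generate_surface(0.0, 4.0, (128, 128), 1.0, seed=0)
        assert s.total_span_um == 0.0
        assert s.empirical_rms_um == 0.0

    def test_rms_and_normality(self):
        s = generate_surface(0.6, 4.0, (512, 512), 1.0, seed=1)
        assert 0.54 <= s.empirical_rms_um <= 0.66
        # Gaussian random field: heights pass normality (subsampled beyond
        # the correlation length so draws are near-independent)
        sub = s.height_um[::16, ::16].ravel()
        assert stats.normaltest(sub).pvalue > 0.01

    def test_autocorrelation_length(self):
        # independent statistical oracle: empirical autocorrelation at lag
        # corr_length should be ~exp(-1) for R(d) = rms^2 exp(-d^2/l^2)
        s = generate_surface(1.0, 8.0, (512, 512), 1.0, seed=2)
        h = s.height_um - s.height_um.mean()
        lag = 8
        num = (h[:, :-lag] * h[:, lag:]).mean()
        rho = num / h.var()
        assert rho == pytest.approx(np.exp(-1.0), abs=0.06)

    def test_aliasing_guard(self):
        with pytest.raises(ValueError):
            generate_surface(0.5, 1.5, (64, 64), 1.0)

    def test_preset_span_supports_full_phase_wrap(self):
        s = surface_from_preset("effective", (512, 512), 1.0, seed=3)
        assert s.total_span_um >= min_span_for_full_phase(0.9, 0.5)
        # => single-pass phase span >= 2 pi at lambda=0.9 um, delta n = 0.5
        beam = BeamSpec(psf4f_fwhm_um=0.0)
        scr = phase_screen(s, (0, 0), beam, round_trip=False)
        assert scr.theta.max() - scr.theta.min() >= 2 * np.pi

    def test_preset_roughness_ordering(self):
        rms = {
            name: surface_from_preset(name, (128, 128), 1.0, seed=0).rms_roughness_um
            for name in ("1500-grit", "2000-grit", "3um-lapped")
        }
        assert rms["1500-grit"] > rms["2000-grit"] > rms["3um-lapped"]


class TestMinSpan:
    def test_exact_criterion_value(self):
        # 2 pi single-pass span at 900 nm through dn=0.5 glass
        assert min_span_for_full_phase(0.9, 0.5) == pytest.approx(1.8, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            min_span_for_full_phase(0.0, 0.5)


class TestPhaseScreen:
    def test_flat_surface_gives_zero_screen(self):
        s = generate_surface(0.0, 4.0, (64, 64), 1.0, seed=0)
        scr = phase_screen(s, (0, 0), BeamSpec())
        assert np.all(scr.theta == 0.0)

    def test_exact_two_pi_span(self):
        # a ramp spanning exactly 1.8 um at lambda=0.9, dn=0.5, no smoothing,
        # single pass -> phase span exactly 2 pi
        h = np.tile(np.linspace(0.0, 1.8, 128), (64, 1))
        s = DiffuserSurface(h, 1.0, 0.5, 4.0, delta_n=0.5)
        scr = phase_screen(s, (0, 0), BeamSpec(psf4f_fwhm_um=0.0), round_trip=False)
        assert scr.theta.max() - scr.theta.min() == pytest.approx(2 * np.pi, rel=1e-12)

    def test_round_trip_doubles_phase(self):
        s = generate_surface(0.5, 4.0, (64, 64), 1.0, seed=4)
        beam = BeamSpec(psf4f_fwhm_um=1.5)
        single = phase_screen(s, (0, 0), beam, round_trip=False)
        double = phase_screen(s, (0, 0), beam, round_trip=True)
        np.testing.assert_allclose(double.theta, 2.0 * single.theta, rtol=1e-12)

    @pytest.mark.parametrize("scale", [0.25, 3.0])
    def test_phase_linearity_in_delta_n(self, scale):
        base = generate_surface(0.5, 4.0, (64, 64), 1.0, seed=4, delta_n=0.5)
        scaled = DiffuserSurface(base.height_um, 1.0, 0.5, 4.0,
                                 delta_n=0.5 * scale)
        beam = BeamSpec(psf4f_fwhm_um=1.5)
        t1 = phase_screen(base, (0, 0), beam).theta
        t2 = phase_screen(scaled, (0, 0), beam).theta
        np.testing.assert_allclose(t2, scale * t1, rtol=1e-10)

    def test_smoothing_reduces_variance(self):
        s = generate_surface(0.5, 4.0, (128, 128), 1.0, seed=5)
        raw = phase_screen(s, (0, 0), BeamSpec(psf4f_fwhm_um=0.0)).theta
        smooth = phase_screen(s, (0, 0), BeamSpec(psf4f_fwhm_um=3.0)).theta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            wide_relay = BeamSpec(psf4f_fwhm_um=40.0)
        very = phase_screen(s, (0, 0), wide_relay).theta
        assert smooth.var() < raw.var()
        assert very.var() < 0.05 * raw.var()  # total-smoothing limit: ~constant

    def test_offset_out_of_bounds(self):
        s = generate_surface(0.5, 4.0, (64, 64), 1.0, seed=0)
        with pytest.raises(ValueError):
            phase_screen(s, (1000.0, 0.0), BeamSpec(), window_shape=(64, 64))

    def test_sampler_matches_window(self):
        s = generate_surface(0.5, 4.0, (64, 64), 1.0, seed=6)
        sampler = ScreenSampler(s, BeamSpec(psf4f_fwhm_um=1.0))
        xs = np.array([3.0, 10.0, 20.0])
        ys = np.array([5.0, 5.0, 12.0])
        vals = sampler.sample(xs, ys, (0.0, 0.0))
        for x, y, v in zip(xs, ys, vals):
            assert v == pytest.approx(sampler.theta_field[int(y), int(x)], abs=0.5)


class TestBeamSpec:
    def test_wavenumber(self):
        assert BeamSpec(wavelength_um=0.9).k == pytest.approx(2 * np.pi / 0.9)

    def test_warns_when_relay_psf_too_large(self):
        with pytest.warns(UserWarning):
            BeamSpec(main_psf_fwhm_um=4.2, psf4f_fwhm_um=6.0)


class TestMotionSchedule:
    def test_rotation_step_at_stated_speeds(self):
        # ~9 mm/s rim velocity against a 20 kHz A-scan rate -> 0.45 um/A-scan
        offs = motion_schedule("rotate", 9.0, ascan_rate_hz=20_000, n_ascans=10)
        assert offs[1, 0] - offs[0, 0] == pytest.approx(0.45)

    def test_translation_step(self):
        offs = motion_schedule("translate", 0.3, frame_period_s=0.05, n_frames=4)
        np.testing.assert_allclose(offs[:, 0], [0.0, 15.0, 30.0, 45.0])

    def test_static(self):
        offs = motion_schedule("static", 1.0, n_frames=5)
        assert np.all(offs == 0.0)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            motion_schedule("translate", -1.0, frame_period_s=0.1, n_frames=2)


class TestScreenDecorrelation:
    def test_zero_displacement_full_correlation(self):
        s = generate_surface(0.6, 4.0, (128, 256), 1.0, seed=7)
        df = screen_decorrelation(s, [(0, 0), (0, 0)], BeamSpec(psf4f_fwhm_um=1.0))
        assert df["correlation"].iloc[1] == pytest.approx(1.0)

    def test_monte_carlo_decorrelation_curve(self):
        # oracle: aggregate over many independent surfaces; far displacement
        # (>> corr length and beam PSF) decorrelates, one corr length is
        # intermediate
        far, mid = [], []
        beam = BeamSpec(psf4f_fwhm_um=1.0)
        for seed in range(50):
            s = generate_surface(0.6, 4.0, (96, 192), 1.0, seed=100 + seed)
            df = screen_decorrelation(
                s, [(0, 0), (4.0, 0), (60.0, 0)], beam, window_shape=(96, 120)
            )
            mid.append(df["correlation"].iloc[1])
            far.append(df["correlation"].iloc[2])
        assert abs(np.mean(far)) < 0.1
        assert 0.15 < np.mean(mid) < 0.9

    def test_requires_two_offsets(self):
        s = generate_surface(0.6, 4.0, (64, 64), 1.0, seed=0)
        with pytest.raises(ValueError):
            screen_decorrelation(s, [(0, 0)], BeamSpec())
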