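"""Spectral-domain synthesis and the reconstruction chain."""

import numpy as np
import pytest

from smoct import (
    NoSignalError,
    average_and_display,
    default_k_axis,
    estimate_dispersion,
    exclude_frames,
    reconstruct,
    simulate_spectra,
)
from smoct.recon import _dispersion_objective
from smoct.speckle import RAYLEIGH_CONTRAST


class TestSimulateSpectra:
    def test_no_scatterers_gives_pure_background(self):
        raw = simulate_spectra((np.array([]), np.array([])))
        np.testing.assert_allclose(raw.spectra[:, 0], raw.source_spectrum, rtol=1e-12)

    def test_fringe_period_of_single_reflector(self):
        z = 200.0
        raw = simulate_spectra(([0.5], [z]))
        # interference term ~ cos(2 k z): spectral fringe period pi/z in k
        ac = raw.spectra[:, 0] - raw.source_spectrum
        zero_crossings = np.diff(np.sign(ac - ac.mean())).nonzero()[0]
        mean_half_period = np.diff(zero_crossings).mean() * raw.dk
        assert mean_half_period == pytest.approx(np.pi / z / 2.0, rel=0.05)

    def test_alias_depth_rejected(self):
        raw_k = default_k_axis()
        z_max = np.pi / (2 * (raw_k[1] - raw_k[0]))
        with pytest.raises(ValueError):
            simulate_spectra(([1.0], [z_max * 1.1]))


class TestReconstruct:
    @pytest.mark.parametrize("z", [100.0, 200.0, 517.0, 1100.0])
    def test_peak_depth_index(self, z):
        raw = simulate_spectra(([1.0], [z]))
        tomo = reconstruct(raw)
        peak = int(np.argmax(tomo.magnitude[:, 0]))
        assert peak == round(z / raw.depth_pitch_um)

    def test_zero_input_gives_zero_ascan(self):
        raw = simulate_spectra((np.array([]), np.array([])))
        tomo = reconstruct(raw)
        np.testing.assert_allclose(tomo.magnitude, 0.0, atol=1e-6)

    def test_two_reflectors_two_peaks(self):
        raw = simulate_spectra(([1.0, 0.8], [300.0, 700.0]))
        mag = reconstruct(raw).magnitude[:, 0]
        dz = raw.depth_pitch_um
        for z in (300.0, 700.0):
            i = round(z / dz)
            assert mag[i] > 10 * np.median(mag)

    def test_compensation_sharpens_peak(self):
        beta = 50.0
        raw = simulate_spectra(([1.0], [400.0]), beta=beta)
        assert (
            reconstruct(raw, beta_comp=beta).magnitude.max()
            > 2.0 * reconstruct(raw, beta_comp=0.0).magnitude.max()
        )

    def test_dft_oracle_agreement(self):
        # independent DFT of the analytically constructed fringe
        z, a = 350.0, 0.7
        raw = simulate_spectra(([a], [z]))
        k = raw.k_axis
        fringe = (raw.spectra[:, 0] - raw.source_spectrum) * np.hanning(len(k))
        oracle = np.abs(np.fft.fft(fringe))[: len(k) // 2]
        np.testing.assert_allclose(
            reconstruct(raw).magnitude[:, 0], oracle, rtol=1e-10
        )


class TestEstimateDispersion:
    def test_zero_dispersion_recovered_near_zero(self):
        raw = simulate_spectra(([1.0, 0.6], [300.0, 800.0]), beta=0.0)
        beta_hat = estimate_dispersion(raw, bracket=(-60.0, 60.0))
        assert abs(beta_hat) < 1.0

    def test_recovery_within_two_percent_and_grid_oracle(self):
        beta = 40.0
        rng = np.random.default_rng(6)
        a = rng.uniform(0.5, 1.5, 3)
        z = rng.uniform(200, 1000, 3)
        raw = simulate_spectra((a, z), beta=beta)
        beta_hat = estimate_dispersion(raw, bracket=(0.0, 100.0))
        assert abs(beta_hat - beta) / beta < 0.02
        # dense grid search over the same objective must agree with the
        # scalar minimiser
        grid = np.linspace(30, 50, 201)
        obj = [_dispersion_objective(raw, b, 0.05) for b in grid]
        beta_grid = grid[int(np.argmin(obj))]
        assert abs(beta_hat - beta_grid) <= 0.2

    def test_amplitude_scale_invariance(self):
        raw = simulate_spectra(([1.0, 0.9, 0.4], [250.0, 600.0, 900.0]), beta=35.0)
        b1 = estimate_dispersion(raw, bracket=(0.0, 80.0))
        raw.spectra = raw.spectra * 137.0
        raw.source_spectrum = raw.source_spectrum * 137.0
        b2 = estimate_dispersion(raw, bracket=(0.0, 80.0))
        assert b1 == pytest.approx(b2, abs=1e-6)

    def test_median_recovery_over_random_betas(self, dispersion_recovery):
        assert dispersion_recovery["rel_error"].median() < 0.02

    def test_no_signal_error(self):
        k = default_k_axis()
        rng = np.random.default_rng(0)
        from smoct import RawSpectra

        flat = RawSpectra(
            spectra=1.0 + 0.01 * rng.random((len(k), 2)),
            k_axis=k,
            source_spectrum=np.ones(len(k)),
        )
        with pytest.raises(NoSignalError):
            estimate_dispersion(flat)


class TestExcludeFrames:
    def test_identical_frames_all_kept(self):
        frames = np.tile(np.random.default_rng(0).random((1, 16, 16)), (5, 1, 1))
        kept, report = exclude_frames(frames, 0.99)
        assert kept.shape[0] == 5
        assert report["kept"].all()

    def test_noise_frame_dropped(self):
        rng = np.random.default_rng(1)
        good = np.tile(rng.random((1, 32, 32)), (9, 1, 1))
        noise = rng.random((1, 32, 32))
        frames = np.concatenate([good, noise])
        kept, report = exclude_frames(frames, 0.5)
        assert kept.shape[0] == 9
        assert report.loc[~report["kept"], "frame"].tolist() == [9]

    def test_threshold_minus_one_keeps_all(self):
        rng = np.random.default_rng(2)
        frames = rng.random((6, 8, 8))
        kept, _ = exclude_frames(frames, -1.0)
        assert kept.shape[0] == 6

    def test_all_excluded_raises_with_advice(self):
        rng = np.random.default_rng(3)
        frames = rng.random((4, 16, 16))
        with pytest.raises(ValueError, match="threshold"):
            exclude_frames(frames, 1.0)


class TestAverageAndDisplay:
    def test_single_frame_identity(self):
        frame = np.random.default_rng(0).random((1, 8, 8))
        mean, _ = average_and_display(frame)
        np.testing.assert_array_equal(mean, frame[0])

    def test_linear_not_log_averaging(self):
        frames = np.stack([np.full((4, 4), 2.0), np.full((4, 4), 4.0)])
        mean, db = average_and_display(frames)
        np.testing.assert_allclose(mean, 3.0)
        np.testing.assert_allclose(db, 20 * np.log10(3.0 + 1e-12 * 3.0))

    def test_log_before_average_differs(self):
        # Jensen guard: averaging after the log is NOT what the chain does
        frames = np.stack([np.full((4, 4), 1.0), np.full((4, 4), 9.0)])
        mean, db = average_and_display(frames)
        log_mean_of_logs = 20 * np.log10(frames).mean(axis=0)
        assert db[0, 0] > log_mean_of_logs[0, 0]


class TestEndToEndConsistency:
    def test_spectral_path_reproduces_speckle_contrast(self):
        # dense random columns through the spectral front end must give the
        # same fully developed speckle statistics as the direct phasor model
        rng = np.random.default_rng(7)
        cols = [(np.ones(500), rng.uniform(250, 450, size=500)) for _ in range(150)]
        raw = simulate_spectra(cols, seed=1)
        mag = reconstruct(raw).magnitude
        band = mag[150:200, :]
        contrast = (band.std(axis=1) / band.mean(axis=1)).mean()
        assert contrast == pytest.approx(RAYLEIGH_CONTRAST, rel=0.05)
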