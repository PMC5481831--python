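"""Forward model: phasor sums, speckle statistics, washout, frame simulation."""

import numpy as np
import pytest

from smoct import (
    BeamSpec,
    FrameStack,
    NoiseModel,
    ScreenSampler,
    VolumeSpec,
    generate_surface,
    generate_uniform_field,
    simulate_frames,
    voxel_frames,
    voxel_signal,
    washout_factor,
)
from smoct.speckle import RAYLEIGH_CONTRAST
from smoct.studies import iid_speckle_stack, interframe_correlation


class TestVoxelSignal:
    def test_single_scatterer_is_speckle_free(self):
        per_frame, avg = voxel_signal([0.7], [1.3], np.random.uniform(0, 7, (5, 1)))
        np.testing.assert_allclose(per_frame, 0.7, rtol=1e-12)
        assert avg == pytest.approx(0.7)

    def test_persistent_destructive_interference(self):
        per_frame, avg = voxel_signal([1.0, 1.0], [0.0, np.pi], np.zeros((3, 2)))
        np.testing.assert_allclose(per_frame, 0.0, atol=1e-12)
        assert avg == pytest.approx(0.0, abs=1e-12)

    def test_empty_voxel_returns_zero(self):
        per_frame, avg = voxel_signal([], [], np.zeros((4, 0)))
        assert avg == 0.0
        np.testing.assert_array_equal(per_frame, np.zeros(4))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            voxel_signal([1.0, 2.0], [0.0], np.zeros((2, 2)))


class TestSpeckleStatistics:
    def test_single_frame_rayleigh_contrast(self, rayleigh_pixels):
        c = rayleigh_pixels.std() / rayleigh_pixels.mean()
        assert c == pytest.approx(RAYLEIGH_CONTRAST, abs=0.01)

    def test_nine_averages_threefold_reduction(self, iid_stack):
        c1 = iid_stack[0].std() / iid_stack[0].mean()
        avg9 = iid_stack[:9].mean(axis=0)
        c9 = avg9.std() / avg9.mean()
        assert c1 / c9 == pytest.approx(3.0, abs=0.1)

    def test_large_m_limit_converges_to_rayleigh_mean(self):
        # M -> inf SM pixel value per voxel -> a sqrt(N pi)/2 for N=20
        n = 20
        frames = iid_speckle_stack(2_000, n, 1_000, seed=9)
        limit = frames.mean(axis=0)
        expected = np.sqrt(n * np.pi) / 2.0
        assert np.median(np.abs(limit - expected) / expected) < 0.03

    def test_mean_preserved_under_averaging(self, iid_stack):
        m1 = iid_stack[0].mean()
        m100 = iid_stack.mean(axis=0).mean()
        assert m100 == pytest.approx(m1, rel=0.01)


class TestWashout:
    def test_no_phase_change_no_attenuation(self):
        assert washout_factor(0) == 1.0

    def test_monotone_nonincreasing(self):
        ks = [0, 1, 2, 4, 9, 19, 49]
        vals = [washout_factor(k) for k in ks]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_large_k_asymptote(self):
        # mean resultant length of K+1 uniform phasors -> sqrt(pi/4)/sqrt(K+1)
        k = 199
        assert washout_factor(k) == pytest.approx(
            np.sqrt(np.pi / 4.0 / (k + 1)), rel=0.02
        )

    def test_monte_carlo_oracle_agreement(self):
        # independent direct simulation with a different stream
        rng = np.random.default_rng(777)
        k = 4
        sample = np.abs(
            np.exp(1j * rng.uniform(0, 2 * np.pi, (100_000, k + 1))).mean(axis=1)
        ).mean()
        assert washout_factor(k) == pytest.approx(sample, rel=0.01)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            washout_factor(-1)


@pytest.fixture(scope="module")
def small_scene():
    volume = VolumeSpec(60.0, 16.0, 40.0, 2.0, 2.0)
    field = generate_uniform_field(volume, 12.0, seed=21)
    beam = BeamSpec()
    surface = generate_surface(
        2.0, 1.2, (int(80 / 0.5), int(400 / 0.5)), 0.5, seed=22
    )
    sampler = ScreenSampler(surface, beam)
    offsets = np.zeros((12, 2))
    offsets[:, 0] = 10.0 + 8.0 * np.arange(12)
    offsets[:, 1] = 10.0
    return volume, field, beam, sampler, offsets


class TestSimulateFrames:
    def test_conventional_frames_identical(self, small_scene):
        volume, field, beam, sampler, offsets = small_scene
        stack = simulate_frames(field, beam, None, offsets[:4],
                                mode="conventional", seed=0)
        for m in range(1, 4):
            np.testing.assert_array_equal(stack.data[0], stack.data[m])

    def test_flat_diffuser_reproduces_conventional_bit_exactly(self, small_scene):
        volume, field, beam, _, offsets = small_scene
        flat = generate_surface(0.0, 1.2, (160, 800), 0.5, seed=0)
        sampler = ScreenSampler(flat, beam)
        noise = NoiseModel(additive_floor=0.3)
        sm = simulate_frames(field, beam, sampler, offsets[:3], noise=noise,
                             mode="sm", seed=5)
        conv = simulate_frames(field, beam, None, offsets[:3], noise=noise,
                               mode="conventional", seed=5)
        np.testing.assert_array_equal(sm.data, conv.data)

    def test_modulated_frames_decorrelate(self, small_scene):
        volume, field, beam, sampler, offsets = small_scene
        stack = simulate_frames(field, beam, sampler, offsets, mode="sm", seed=1)
        flat_frames = stack.data.reshape(stack.n_frames, -1)
        assert interframe_correlation(flat_frames) < 0.1

    def test_single_scatterer_voxel_has_no_interframe_variance(self):
        volume = VolumeSpec(40.0, 8.0, 20.0, 2.0, 2.0)
        pos = np.array([[20.0, 4.0, 10.0]])
        from smoct import ScattererField

        field = ScattererField(pos, [1.0], ["background"], volume)
        beam = BeamSpec()
        surface = generate_surface(2.0, 1.2, (100, 400), 0.5, seed=3)
        sampler = ScreenSampler(surface, beam)
        offsets = np.zeros((6, 2))
        offsets[:, 0] = 10 + 20.0 * np.arange(6)
        offsets[:, 1] = 10.0
        stack = simulate_frames(field, beam, sampler, offsets, mode="sm", seed=0)
        assert np.ptp(stack.data, axis=0).max() == pytest.approx(0.0, abs=1e-9)

    def test_requires_sampler_in_sm_mode(self, small_scene):
        volume, field, beam, _, offsets = small_scene
        with pytest.raises(ValueError):
            simulate_frames(field, beam, None, offsets, mode="sm")


class TestContainers:
    def test_frame_stack_validation(self):
        with pytest.raises(ValueError):
            FrameStack(np.full((2, 4, 4), -1.0), 2.0, 2.0)
        with pytest.raises(ValueError):
            FrameStack(np.ones((4, 4)), 2.0, 2.0)

    def test_frame_stack_average(self):
        stack = FrameStack(np.stack([np.full((4, 4), 2.0), np.full((4, 4), 4.0)]),
                           2.0, 2.0)
        np.testing.assert_allclose(stack.average(), 3.0)
        np.testing.assert_allclose(stack.average(1), 2.0)

    def test_noise_model_validation(self):
        with pytest.raises(ValueError):
            NoiseModel(additive_floor=-0.1)

    def test_voxel_frames_matches_voxel_signal(self, rng):
        a = rng.random((3, 5))
        phi = rng.uniform(0, 2 * np.pi, (3, 5))
        theta = rng.uniform(0, 2 * np.pi, (4, 3, 5))
        out = voxel_frames(a, phi, theta)
        for v in range(3):
            per_frame, _ = voxel_signal(a[v], phi[v], theta[:, v, :])
            np.testing.assert_allclose(out[:, v], per_frame, rtol=1e-12)
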