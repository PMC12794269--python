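import numpy as np
import pytest

from limblab.core import ExperimentLedger, LimbMetadata, ParameterError, VoxelGrid
from limblab.preprocess import (
    CleanConfig,
    clamp_intensity,
    clean_volume,
    gaussian_smooth,
    lowpass_filter,
    mirror_grid,
    resample_grid,
)


def grid_of(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data, dtype=float), spacing)


class TestClamp:
    def test_below_floor_zeroed_above_ceiling_clamped(self):
        g = grid_of(np.array([10.0, 100.0, 250.0]).reshape(3, 1, 1))
        out = clamp_intensity(g, 50, 200)
        assert out.data.ravel().tolist() == [0.0, 100.0, 200.0]

    def test_identity_window(self, rng):
        data = rng.uniform(10, 90, (5, 5, 5))
        g = grid_of(data)
        out = clamp_intensity(g, data.min(), data.max())
        assert np.allclose(out.data, data)

    def test_idempotent(self, rng):
        g = grid_of(rng.uniform(0, 300, (6, 6, 6)))
        once = clamp_intensity(g, 50, 200)
        twice = clamp_intensity(once, 50, 200)
        assert np.array_equal(once.data, twice.data)

    def test_invalid_window(self):
        with pytest.raises(ParameterError):
            clamp_intensity(grid_of(np.zeros((2, 2, 2))), 200, 50)


class TestMirror:
    def test_involution(self, rng):
        g = grid_of(rng.uniform(0, 1, (4, 5, 6)))
        assert np.array_equal(mirror_grid(mirror_grid(g, 1), 1).data, g.data)

    def test_index_arithmetic(self):
        data = np.zeros((10, 3, 3))
        data[2, 1, 1] = 1.0
        out = mirror_grid(grid_of(data), axis=0)
        assert out.data[7, 1, 1] == 1.0 and out.data.sum() == 1.0

    def test_bad_axis(self):
        with pytest.raises(ParameterError):
            mirror_grid(grid_of(np.zeros((2, 2, 2))), 3)


class TestGaussian:
    def test_constant_invariance(self):
        g = grid_of(np.full((20, 20, 20), 7.0))
        assert np.abs(gaussian_smooth(g).data - 7.0).max() < 1e-9

    def test_impulse_response_std(self):
        data = np.zeros((97, 97, 97))
        data[48, 48, 48] = 1.0
        out = gaussian_smooth(grid_of(data), sigma=(6, 6, 6)).data
        for axis in range(3):
            other = tuple(a for a in range(3) if a != axis)
            marginal = out.sum(axis=other)
            idx = np.arange(97)
            mu = (idx * marginal).sum() / marginal.sum()
            std = np.sqrt(((idx - mu) ** 2 * marginal).sum() / marginal.sum())
            assert abs(std - 6.0) < 0.05

    def test_mass_conserved_for_interior_signal(self):
        data = np.zeros((97, 97, 97))
        data[40:57, 40:57, 40:57] = 3.0
        out = gaussian_smooth(grid_of(data)).data
        assert abs(out.sum() - data.sum()) / data.sum() < 1e-3

    def test_zero_sigma_is_identity(self, rng):
        g = grid_of(rng.uniform(0, 1, (8, 8, 8)))
        assert np.array_equal(gaussian_smooth(g, (0, 0, 0)).data, g.data)


def axial_cosine(freq, n=200):
    x = np.arange(n)
    data = np.cos(2 * np.pi * freq * x)[:, None, None] * np.ones((1, 4, 4))
    return grid_of(data)


class TestLowpass:
    def test_constant_preserved(self):
        g = grid_of(np.full((16, 16, 16), 3.5))
        assert np.abs(lowpass_filter(g).data - 3.5).max() < 1e-9

    @pytest.mark.parametrize(
        "freq,kept", [(0.02, True), (0.10, False)]
    )
    def test_axial_cosine_pass_and_stop(self, freq, kept):
        g = axial_cosine(freq)
        out = lowpass_filter(g, cutoff=0.05).data
        amp = np.abs(out).max()
        if kept:
            assert amp > 0.99
        else:
            assert amp < 0.01

    def test_bad_cutoff(self):
        with pytest.raises(ParameterError):
            lowpass_filter(grid_of(np.zeros((4, 4, 4))), 0.0)


class TestResample:
    def test_same_shape_identity(self, rng):
        g = grid_of(rng.uniform(0, 1, (9, 9, 9)))
        assert np.abs(resample_grid(g, (9, 9, 9)).data - g.data).max() < 1e-9

    def test_linear_ramp_downsampled_stays_linear(self):
        n = 32
        ramp = np.broadcast_to(np.arange(n, dtype=float)[:, None, None], (n, n, n))
        g = grid_of(np.array(ramp), spacing=(2.0, 2.0, 2.0))
        out = resample_grid(g, (16, 16, 16))
        profile = out.data[:, 8, 8]
        slopes = np.diff(profile)
        assert np.abs(slopes - slopes[0]).max() < 1e-6
        # physical slope preserved: index step doubled, so value step doubles
        assert abs(slopes[0] - 2.0) < 1e-6

    def test_bookkeeping_halving(self):
        g = grid_of(np.zeros((64, 64, 64)), spacing=(0.65, 0.65, 2.0))
        out = resample_grid(g, (32, 32, 32))
        assert out.data.shape == (32, 32, 32)
        assert np.allclose(out.spacing, (1.3, 1.3, 4.0))

    def test_constant_field_exact(self):
        g = grid_of(np.full((12, 10, 8), 4.2))
        out = resample_grid(g, (7, 5, 3))
        assert np.abs(out.data - 4.2).max() < 1e-12


class TestCleanVolume:
    def meta(self, side="right"):
        return LimbMetadata(side, "forelimb", (1.0, 1.0, 1.0))

    def config(self, **kw):
        base = dict(clip_low=10.0, clip_high=90.0)
        base.update(kw)
        return CleanConfig(**base)

    def test_left_limb_mirrored_relative_to_right(self, rng, tmp_path):
        data = rng.uniform(0, 100, (16, 16, 16))
        left = clean_volume(grid_of(data), self.meta("left"), self.config())
        right = clean_volume(grid_of(data), self.meta("right"), self.config())
        assert np.allclose(left.data, np.flip(right.data, axis=0), atol=1e-9)

    def test_defaults_recorded_in_ledger(self, rng, tmp_path):
        ledger = ExperimentLedger(tmp_path)
        clean_volume(grid_of(rng.uniform(0, 100, (12, 12, 12))), self.meta(),
                     self.config(), ledger)
        assert ledger.read("sigma") == [6.0, 6.0, 6.0]
        assert ledger.read("cutoff") == 0.05
        assert ledger.read("clip_low") == 10.0
        assert ledger.read("clip_high") == 90.0
        assert ledger.read("mirrored") is False
        assert ledger.read("spacing") == [1.0, 1.0, 1.0]

    def test_all_zero_grid_passes_through(self):
        out = clean_volume(grid_of(np.zeros((8, 8, 8))), self.meta(), self.config())
        assert np.allclose(out.data, 0.0)

    def test_matches_manual_stage_sequence(self, rng):
        data = rng.uniform(0, 120, (16, 16, 16))
        cfg = self.config()
        auto = clean_volume(grid_of(data), self.meta("left"), cfg)
        manual = lowpass_filter(
            gaussian_smooth(
                mirror_grid(clamp_intensity(grid_of(data), 10, 90), 0), cfg.sigma
            ),
            cfg.cutoff,
        )
        assert np.allclose(auto.data, manual.data)

    def test_stage_order_matters(self, rng):
        # permuting clamp and smooth changes the result
        data = rng.uniform(0, 120, (16, 16, 16))
        cfg = self.config()
        pipeline = clean_volume(grid_of(data), self.meta(), cfg)
        permuted = lowpass_filter(
            clamp_intensity(gaussian_smooth(grid_of(data), cfg.sigma), 10, 90),
            cfg.cutoff,
        )
        assert not np.allclose(pipeline.data, permuted.data)

    def test_spectral_power_reduced_on_speckle(self, noisy_phantom_spec):
        from limblab.phantom import make_limb_phantom

        noisy = make_limb_phantom(noisy_phantom_spec)["nuclei"]
        cleaned = clean_volume(
            noisy, self.meta(), self.config(clip_low=1.0, clip_high=150.0)
        )

        def high_power(g):
            spec = np.abs(np.fft.fftn(g.data)) ** 2
            fr = [np.fft.fftfreq(n) for n in g.data.shape]
            r2 = (
                fr[0][:, None, None] ** 2
                + fr[1][None, :, None] ** 2
                + fr[2][None, None, :] ** 2
            )
            return spec[r2 > 0.05**2].sum()

        assert high_power(cleaned) < 0.01 * high_power(noisy)

    def test_validation_error_propagates(self):
        with pytest.raises(ParameterError):
            self.config(clip_low=90.0, clip_high=10.0)
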