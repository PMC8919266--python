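import numpy as np
import pytest
from scipy import ndimage

import cstomo as ct
from cstomo.preprocess import fourier_shift_image


def _series(images, angles):
    return ct.TiltSeries(images=np.asarray(images, dtype=float),
                         angles=np.asarray(angles, dtype=float))


class TestFlatBackground:
    def test_constant_series(self):
        ts = _series(np.full((3, 8, 8), 100.0), [-10, 0, 10])
        bg = ct.estimate_background_flat(ts, (0, 0, 4, 4))
        assert np.allclose(bg.per_tilt, 100.0)

    def test_per_tilt_offsets_recovered(self):
        imgs = np.zeros((3, 8, 8))
        for i, level in enumerate((10.0, 20.0, 30.0)):
            imgs[i] += level
        bg = ct.estimate_background_flat(_series(imgs, [-10, 0, 10]),
                                         (0, 0, 8, 8))
        assert np.allclose(bg.per_tilt, [10.0, 20.0, 30.0])

    def test_poisson_background_within_sampling_error(self):
        rng = np.random.default_rng(0)
        mean = 50.0
        imgs = rng.poisson(mean, size=(3, 100, 100)).astype(float)
        bg = ct.estimate_background_flat(_series(imgs, [-10, 0, 10]),
                                         (0, 0, 100, 100))
        se = np.sqrt(mean / 1e4)
        assert np.all(np.abs(bg.per_tilt - mean) < 3 * se)

    def test_region_outside_rejected(self):
        ts = _series(np.zeros((2, 8, 8)), [0, 10])
        with pytest.raises(ValueError, match="region"):
            ct.estimate_background_flat(ts, (0, 0, 9, 4))


class TestSlabBackground:
    def test_zero_tilt_equals_b0_and_cos_rule(self):
        imgs = np.full((3, 8, 8), 10.0)
        ts = _series(imgs, [-60.0, 0.0, 60.0])
        bg = ct.estimate_background_slab(ts, (0, 0, 8, 8))
        assert bg.value_at(0.0) == pytest.approx(10.0)
        assert bg.value_at(60.0) == pytest.approx(20.0)  # 1/cos(60) = 2

    def test_constructed_slab_removed_to_rounding(self):
        """A series built with exactly the 1/cos rule leaves < 1e-9 residual
        in the empty region after subtraction."""
        angles = np.arange(-60.0, 61.0, 10.0)
        b0 = 7.5
        imgs = np.ones((len(angles), 16, 16))
        imgs *= (b0 / np.cos(np.deg2rad(angles)))[:, None, None]
        ts = _series(imgs, angles)
        bg = ct.estimate_background_slab(ts, (0, 0, 16, 16))
        resid = ct.subtract_background(ts, bg).images
        assert np.abs(resid).max() < 1e-9

    def test_steep_tilt_rejected(self):
        ts = _series(np.zeros((2, 8, 8)), [0.0, 90.0])
        with pytest.raises(ValueError, match="slab"):
            ct.estimate_background_slab(ts, (0, 0, 8, 8))


class TestInvertAndScale:
    def test_all_background_warns_and_zeros(self):
        ts = _series(np.full((2, 8, 8), 100.0), [0, 10])
        bg = ct.estimate_background_flat(ts, (0, 0, 8, 8))
        with pytest.warns(UserWarning, match="all background"):
            out = ct.invert_and_scale(ts, bg)
        assert np.allclose(out.images, 0.0)

    def test_linear_map_values(self):
        imgs = np.full((1, 4, 4), 100.0)
        imgs[0, 0, 0] = 40.0   # darkest pixel
        imgs[0, 1, 1] = 70.0
        ts = _series(imgs, [0.0])
        bg = ct.BackgroundModel(kind="flat", angles=np.array([0.0]),
                                per_tilt=np.array([100.0]), b0=100.0)
        out = ct.invert_and_scale(ts, bg)
        assert out.images[0, 0, 0] == pytest.approx(1.0)
        assert out.images[0, 1, 1] == pytest.approx(0.5)
        assert out.images.max() == pytest.approx(1.0)

    def test_double_inversion_restores_contrast_sign(self, rng):
        imgs = 100.0 - rng.uniform(0, 50, size=(2, 16, 16))
        imgs[:, :4, :4] = 100.0  # empty corner
        ts = _series(imgs, [0.0, 10.0])
        bg = ct.estimate_background_flat(ts, (0, 0, 4, 4))
        once = ct.invert_and_scale(ts, bg)
        bg2 = ct.estimate_background_flat(once, (0, 0, 4, 4))
        # the re-inverted series is all non-positive, so no rescale applies
        with pytest.warns(UserWarning, match="all background"):
            twice = ct.invert_and_scale(once, bg2)
        corr = np.corrcoef(twice.images.ravel(), ts.images.ravel())[0, 1]
        assert corr > 0.99


class TestCentering:
    def test_on_axis_particle_is_pure_crop(self, rng):
        imgs = rng.standard_normal((3, 32, 32))
        ts = _series(imgs, [-30.0, 0.0, 30.0])
        out = ct.center_on_tilt_axis(ts, ct.ParticleCoordinate(), box=16)
        assert out.images.shape == (3, 16, 16)
        assert np.allclose(out.images, imgs[:, 8:24, 8:24], atol=1e-9)

    def test_zero_tilt_shift_is_minus_x(self):
        coord = ct.ParticleCoordinate(x=10.0, z=5.0)
        assert -coord.projected_u(0.0) == pytest.approx(-10.0)

    def test_integer_fourier_shift_equals_roll(self, rng):
        img = rng.standard_normal((16, 16))
        shifted = fourier_shift_image(img, (-3.0, 0.0))
        assert np.abs(shifted - np.roll(img, -3, axis=0)).max() < 1e-9

    def test_track_leaving_fov_rejected(self):
        ts = _series(np.zeros((2, 32, 32)), [0.0, 45.0])
        coord = ct.ParticleCoordinate(x=14.0)
        with pytest.raises(ValueError, match="field of view"):
            ct.center_on_tilt_axis(ts, coord, box=16)


class TestFullChain:
    def test_off_axis_particle_recentred_to_volume_center(self):
        """simulate off-axis -> flat background -> invert -> center ->
        CS-TV^2 puts the particle's center of mass within 1 voxel of the
        volume center."""
        n_big, box, dz, dx = 96, 48, 7, -11
        small = ct.make_phantom(ct.PhantomSpec(kind="capsid_shell", size=32,
                                               ndim=2, seed=5))
        big = np.zeros((n_big, n_big))
        z0, x0 = (n_big - 32) // 2 + dz, (n_big - 32) // 2 + dx
        big[z0:z0 + 32, x0:x0 + 32] = small.data
        angles = ct.angular_scheme(-60, 60, 3)
        geom = ct.TiltGeometry(angles)
        noise = ct.NoiseSpec(dose=50.0, background=2.0, seed=3)
        dark = ct.simulate_tilt_series(ct.Volume(big), angles, noise,
                                       return_mode="counts_dark")
        bg = ct.estimate_background_flat(dark, (0, 0, 1, 12))
        inv = ct.invert_and_scale(dark, bg)
        centered = ct.center_on_tilt_axis(
            inv, ct.ParticleCoordinate(x=dx, z=dz), box=box)
        cfg = ct.SolverConfig(lam=0.02, iterations=200)
        vol, _ = ct.cstv2_reconstruct(centered, geom, cfg)
        com = ndimage.center_of_mass(vol.data)
        center = ((box - 1) / 2.0,) * 2
        assert np.hypot(com[0] - center[0], com[1] - center[1]) < 1.0
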