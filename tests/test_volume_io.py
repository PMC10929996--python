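"""Volume I/O, HU preprocessing, resampling and patch extraction."""

import numpy as np
import pytest

from coretr import volume_io as vio
from coretr.volume_io import (CTVolume, SegMask, crop_random_patches,
                              minmax_normalize, read_volume, resample_uniform,
                              truncate_hu, write_volume)


@pytest.fixture
def hu_volume():
    rng = np.random.default_rng(0)
    v = rng.uniform(-1200, 3500, size=(12, 10, 8)).astype(np.float32)
    return CTVolume(voxels=v, spacing=(1.0, 1.0, 3.0))


class TestNiftiIO:
    def test_round_trip_identity(self, tmp_path, hu_volume):
        p = tmp_path / "vol.nii.gz"
        write_volume(hu_volume, p)
        back = read_volume(p)
        np.testing.assert_allclose(back.voxels, hu_volume.voxels, rtol=1e-6)
        assert back.spacing == pytest.approx(hu_volume.spacing)
        assert not back.normalized

    def test_spacing_passthrough(self, tmp_path):
        vol = CTVolume(voxels=np.zeros((4, 4, 4), np.float32), spacing=(1.0, 1.0, 3.0))
        p = tmp_path / "s.nii.gz"
        write_volume(vol, p)
        assert read_volume(p).spacing == pytest.approx((1.0, 1.0, 3.0))

    def test_missing_file(self, tmp_path):
        with pytest.raises(vio.MissingFileError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_4d_image_rejected(self, tmp_path):
        import SimpleITK as sitk
        img = sitk.GetImageFromArray(np.zeros((2, 3, 4, 5), np.float32), isVector=False)
        p = str(tmp_path / "4d.nii.gz")
        sitk.WriteImage(img, p)
        with pytest.raises(vio.NotA3DImageError, match="3D"):
            read_volume(p)

    def test_unreadable_header(self, tmp_path):
        p = tmp_path / "garbage.nii"
        p.write_bytes(b"this is not a nifti header at all")
        with pytest.raises(vio.UnreadableHeaderError):
            read_volume(p)


class TestPreprocessing:
    @pytest.mark.parametrize("value,expected", [(-2000.0, -1024.0), (500.0, 500.0),
                                                (4000.0, 3068.0)])
    def test_truncate_clamps(self, value, expected):
        vol = CTVolume(voxels=np.full((2, 2, 2), value, np.float32))
        assert truncate_hu(vol).voxels.flat[0] == expected

    def test_truncate_rejects_bad_window(self, hu_volume):
        with pytest.raises(ValueError):
            truncate_hu(hu_volume, lo=100, hi=100)

    @pytest.mark.parametrize("value,expected", [(-1024.0, 0.0), (3068.0, 1.0),
                                                (1022.0, 0.5)])
    def test_normalize_fixed_window(self, value, expected):
        # (1022 + 1024) / 4092 = 0.5 by hand
        vol = CTVolume(voxels=np.full((2, 2, 2), value, np.float32))
        out = minmax_normalize(vol)
        assert out.normalized
        np.testing.assert_allclose(out.voxels, expected, atol=1e-6)

    def test_normalize_twice_rejected(self):
        vol = CTVolume(voxels=np.zeros((2, 2, 2), np.float32))
        with pytest.raises(ValueError, match="already normalized"):
            minmax_normalize(minmax_normalize(vol))

    def test_truncate_then_normalize_hits_bounds_exactly(self, hu_volume):
        out = minmax_normalize(truncate_hu(hu_volume))
        assert out.voxels.min() == 0.0 and out.voxels.max() == 1.0


class TestResampling:
    def test_noop_resample_is_identity(self, hu_volume):
        out = resample_uniform(hu_volume, hu_volume.spacing, method="linear")
        np.testing.assert_array_equal(out.voxels, hu_volume.voxels)

    def test_dimension_formula(self):
        vol = CTVolume(voxels=np.zeros((10, 10, 10), np.float32), spacing=(2.0, 2.0, 2.0))
        out = resample_uniform(vol, (1.0, 1.0, 1.0), method="linear")
        assert out.voxels.shape == (20, 20, 20)
        assert out.spacing == pytest.approx((1.0, 1.0, 1.0))

    @pytest.mark.parametrize("method", ["windowed-sinc", "linear", "nearest"])
    def test_constant_volume_stays_constant(self, method):
        vol = CTVolume(voxels=np.full((8, 8, 8), 37.0, np.float32), spacing=(1.0, 1.0, 2.0))
        out = resample_uniform(vol, (1.0, 1.0, 1.0), method=method)
        # ITK's Hamming-windowed sinc kernel is not renormalized, so a constant
        # image is preserved only to ~0.5%; linear/nearest are exact
        tol = 0.5 if method == "windowed-sinc" else 1e-3
        np.testing.assert_allclose(out.voxels, 37.0, atol=tol)

    def test_round_trip_smooth_volume(self):
        h, w, d = np.meshgrid(*[np.linspace(0, np.pi, 16)] * 3, indexing="ij")
        smooth = (np.sin(h) * np.sin(w) * np.sin(d) * 100).astype(np.float32)
        vol = CTVolume(voxels=smooth, spacing=(2.0, 2.0, 2.0))
        down = resample_uniform(vol, (1.0, 1.0, 1.0), method="windowed-sinc")
        back = resample_uniform(down, (2.0, 2.0, 2.0), method="windowed-sinc")
        assert back.voxels.shape == smooth.shape
        interior = (slice(3, -3),) * 3
        assert np.abs(back.voxels - smooth)[interior].max() < 5.0

    def test_mask_resample_stays_binary(self):
        rng = np.random.default_rng(3)
        m = SegMask(voxels=(rng.random((9, 9, 9)) < 0.3).astype(np.uint8),
                    spacing=(1.0, 1.0, 2.5))
        out = resample_uniform(m, (1.0, 1.0, 1.0), method="nearest")
        assert set(np.unique(out.voxels)) <= {0, 1}

    def test_mask_requires_nearest(self):
        m = SegMask(voxels=np.zeros((4, 4, 4), np.uint8))
        with pytest.raises(ValueError, match="nearest"):
            resample_uniform(m, (0.5, 0.5, 0.5), method="linear")

    def test_rejects_nonpositive_spacing(self, hu_volume):
        with pytest.raises(ValueError):
            resample_uniform(hu_volume, (0.0, 1.0, 1.0))


class TestPatchSampling:
    def _pair(self, shape=(40, 40, 40), seed=0):
        rng = np.random.default_rng(seed)
        img = np.clip(rng.random(shape), 0, 1).astype(np.float32)
        msk = np.zeros(shape, np.uint8)
        msk[tuple(s // 2 for s in shape)] = 1
        vol = CTVolume(voxels=img, normalized=True)
        return vol, SegMask(voxels=msk)

    def test_returns_n_patches_of_requested_size(self):
        vol, msk = self._pair()
        patches = crop_random_patches(vol, msk, size=16, n=4,
                                      rng=np.random.default_rng(1))
        assert len(patches) == 4
        assert all(p.image.shape == (16, 16, 16) for p in patches)
        assert all(p.image.shape == p.mask.shape for p in patches)

    def test_forced_foreground_centering(self):
        vol, msk = self._pair()
        patches = crop_random_patches(vol, msk, size=16, n=8, fg_fraction=1.0,
                                      rng=np.random.default_rng(2))
        assert all(p.mask.sum() == 1 for p in patches)

    def test_determinism_under_fixed_seed(self):
        vol, msk = self._pair()
        a = crop_random_patches(vol, msk, size=16, n=4, rng=np.random.default_rng(7))
        b = crop_random_patches(vol, msk, size=16, n=4, rng=np.random.default_rng(7))
        assert [p.corner for p in a] == [p.corner for p in b]
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.image, pb.image)

    def test_corners_stay_in_bounds(self):
        vol, msk = self._pair()
        for p in crop_random_patches(vol, msk, size=16, n=32,
                                     rng=np.random.default_rng(3)):
            assert all(0 <= c and c + 16 <= 40 for c in p.corner)
            assert not p.padded

    def test_small_volume_padded_and_flagged(self):
        vol, msk = self._pair(shape=(10, 40, 40))
        patches = crop_random_patches(vol, msk, size=16, n=2,
                                      rng=np.random.default_rng(4))
        assert all(p.padded for p in patches)
        assert all(p.image.shape == (16, 16, 16) for p in patches)
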