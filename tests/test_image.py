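"""I/O round-trips, normalization and resampling contracts."""

import numpy as np
import pytest

from mpkb.image import (FormatError, SegmentationMask, VolumeImage,
                        normalize_intensity, physical_coordinates, read_volume,
                        resample_onto, resample_to_reference, reslice_view,
                        write_volume)
from mpkb.phantoms import PhantomSpec, ellipsoid_true_volume, rasterize_gland


class TestNiftiIO:
    def test_roundtrip_preserves_intensities_and_metadata(self, rng, tmp_path):
        vol = VolumeImage(rng.standard_normal((16, 16, 16)).astype(np.float32),
                          spacing=(0.5, 0.7, 3.0), origin=(1.0, -2.0, 3.5))
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.intensities, vol.intensities)
        np.testing.assert_allclose(back.spacing, vol.spacing, rtol=1e-6)
        np.testing.assert_allclose(back.origin, vol.origin, atol=1e-5)
        assert back.axis_labels == vol.axis_labels

    def test_axis_labels_follow_header_orientation(self, rng, tmp_path):
        # a header storing axes as (coronal, axial, sagittal) with one flip
        import nibabel as nib
        data = rng.standard_normal((4, 5, 6)).astype(np.float32)
        affine = np.array([[0.0, 0.0, -1.2, 10.0],
                           [0.8, 0.0, 0.0, 0.0],
                           [0.0, 3.0, 0.0, 0.0],
                           [0.0, 0.0, 0.0, 1.0]])
        path = tmp_path / "permuted.nii.gz"
        nib.save(nib.Nifti1Image(data, affine), str(path))
        vol = read_volume(path)
        assert vol.axis_labels == ("coronal", "axial", "sagittal")
        assert vol.spacing == pytest.approx((0.8, 3.0, 1.2))

    def test_truncated_file_raises_format_error(self, rng, tmp_path):
        vol = VolumeImage(rng.standard_normal((8, 8, 8)).astype(np.float32),
                          spacing=(1, 1, 1))
        path = tmp_path / "trunc.nii"
        write_volume(vol, path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(FormatError):
            read_volume(path)

    def test_missing_file_raises_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_volume(tmp_path / "nope.nii.gz")


class TestNormalization:
    def test_zero_mean_unit_sd(self, rng):
        vol = VolumeImage(rng.gamma(2.0, 50.0, (12, 12, 12)), spacing=(1, 1, 1))
        out = normalize_intensity(vol)
        assert abs(out.intensities.mean()) < 1e-5
        assert abs(out.intensities.std() - 1.0) < 1e-5

    def test_invariant_to_positive_affine_rescaling(self, rng):
        data = rng.standard_normal((10, 10, 10))
        a = normalize_intensity(VolumeImage(data, spacing=(1, 1, 1)))
        b = normalize_intensity(VolumeImage(3.7 * data + 42.0, spacing=(1, 1, 1)))
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-5)

    def test_outlier_clipped_to_percentile_bound(self):
        # 1000 values; the single huge outlier must map to the clipped maximum
        vals = np.concatenate([np.linspace(0, 100, 999), [1e6]])
        data = vals.reshape((10, 10, 10))
        out = normalize_intensity(VolumeImage(data, spacing=(1, 1, 1)))
        hi = np.percentile(vals, 99.5)
        clipped = np.clip(vals, np.percentile(vals, 0.5), hi)
        expected_max = (hi - clipped.mean()) / clipped.std()
        # output is float32, so compare at single precision
        assert out.intensities.max() == pytest.approx(expected_max, abs=1e-6)
        # monotone non-decreasing mapping
        order = np.argsort(vals)
        mapped = out.intensities.reshape(-1)[order]
        assert np.all(np.diff(mapped) >= -1e-12)

    def test_idempotent_up_to_clipping(self, rng):
        vol = VolumeImage(rng.standard_normal((10, 10, 10)), spacing=(1, 1, 1))
        once = normalize_intensity(vol)
        twice = normalize_intensity(once)
        assert np.abs(twice.intensities - once.intensities).max() < 1e-3

    def test_constant_image_rejected(self):
        vol = VolumeImage(np.full((5, 5, 5), 7.0), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="constant"):
            normalize_intensity(vol)


class TestResampling:
    def test_identity_resample(self, rng):
        vol = VolumeImage(rng.standard_normal((10, 10, 10)).astype(np.float32),
                          spacing=(1.0, 1.0, 2.0))
        out = resample_to_reference(vol, (1.0, 1.0, 2.0))
        assert out.shape == vol.shape
        np.testing.assert_allclose(out.intensities, vol.intensities, atol=1e-5)

    def test_constant_image_reproduced(self):
        vol = VolumeImage(np.full((8, 8, 8), 3.25, dtype=np.float32),
                          spacing=(1, 1, 1))
        out = resample_to_reference(vol, (0.5, 0.5, 2.0))
        np.testing.assert_allclose(out.intensities, 3.25, atol=1e-4)

    def test_mask_volume_preserved_under_anisotropic_resample(self):
        spec = PhantomSpec(semi_axes=(15, 12, 14), deform_amplitude=0.0, seed=3)
        mask, _ = rasterize_gland(spec, 1.0)
        out = resample_to_reference(mask, (0.5, 0.5, 3.0))
        v_analytic = ellipsoid_true_volume(15, 12, 14)
        v_out = out.labels.sum() * out.voxel_volume_mm3() / 1000.0
        assert abs(v_out - v_analytic) / v_analytic < 0.05
        assert set(np.unique(out.labels)) <= {0, 1}

    def test_volume_conserved_for_six_fold_spacing_ratio(self):
        spec = PhantomSpec(semi_axes=(20, 16, 18), deform_amplitude=0.0, seed=2)
        mask, _ = rasterize_gland(spec, 0.5)
        v0 = mask.labels.sum() * mask.voxel_volume_mm3()
        out = resample_to_reference(mask, (0.5, 0.5, 3.0))
        v1 = out.labels.sum() * out.voxel_volume_mm3()
        assert abs(v1 - v0) / v0 <= 0.05

    def test_single_slice_axis_falls_back_to_linear(self, rng, caplog):
        vol = VolumeImage(rng.standard_normal((8, 8, 1)).astype(np.float32),
                          spacing=(1.0, 1.0, 3.0))
        import logging
        with caplog.at_level(logging.WARNING, logger="mpkb.image"):
            out = resample_to_reference(vol, (0.5, 0.5, 3.0))
        assert out.shape[2] == 1
        assert any("linear" in rec.message for rec in caplog.records)

    def test_physical_extent_preserved_within_one_voxel(self, rng):
        vol = VolumeImage(rng.standard_normal((20, 30, 10)).astype(np.float32),
                          spacing=(1.0, 0.7, 3.5))
        target = (0.5, 0.5, 3.0)
        out = resample_to_reference(vol, target)
        for ax in range(3):
            extent_in = vol.shape[ax] * vol.spacing[ax]
            extent_out = out.shape[ax] * target[ax]
            assert abs(extent_in - extent_out) <= target[ax]


class TestReslicing:
    def test_identity_for_current_view(self, rng):
        vol = VolumeImage(rng.standard_normal((4, 5, 6)), spacing=(1, 2, 3))
        out = reslice_view(vol, "axial")
        np.testing.assert_array_equal(out.intensities, vol.intensities)
        assert out.axis_labels == vol.axis_labels

    def test_double_permutation_composes(self, rng):
        vol = VolumeImage(rng.standard_normal((4, 5, 6)), spacing=(1, 2, 3))
        via_sag = reslice_view(reslice_view(vol, "sagittal"), "coronal")
        direct = reslice_view(vol, "coronal")
        np.testing.assert_array_equal(via_sag.intensities, direct.intensities)
        assert via_sag.spacing == direct.spacing
        assert via_sag.axis_labels == direct.axis_labels

    def test_roundtrip_recovers_original(self, rng):
        vol = VolumeImage(rng.standard_normal((4, 5, 6)), spacing=(1, 2, 3),
                          origin=(0.5, 1.5, -2.0))
        back = reslice_view(reslice_view(vol, "sagittal"), "axial")
        np.testing.assert_array_equal(back.intensities, vol.intensities)
        assert back.spacing == vol.spacing
        assert back.origin == vol.origin

    def test_physical_points_invariant(self, rng):
        vol = VolumeImage(rng.standard_normal((6, 7, 8)), spacing=(1.0, 2.0, 3.0),
                          origin=(4.0, -1.0, 2.0))
        res = reslice_view(vol, "coronal")
        idx = rng.integers(0, (6, 7, 8), size=(5, 3))
        for i, j, k in idx:
            p = physical_coordinates(vol, (i, j, k))
            # locate the same physical point in the resliced grid
            inv = {lbl: ax for ax, lbl in enumerate(res.axis_labels)}
            coord = [0, 0, 0]
            for axis_label, value in zip(("sagittal", "coronal", "axial"), p):
                ax = inv[axis_label]
                coord[ax] = int(round((value - res.origin[ax]) / res.spacing[ax]))
            assert res.intensities[tuple(coord)] == vol.intensities[i, j, k]

    def test_unknown_view_rejected(self, rng):
        vol = VolumeImage(rng.standard_normal((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="unknown view"):
            reslice_view(vol, "oblique")


def test_resample_onto_matches_reference_grid(rng):
    spec = PhantomSpec(semi_axes=(12, 10, 11), deform_amplitude=0.0, seed=5)
    fine, _ = rasterize_gland(spec, 1.0)
    coarse = resample_to_reference(fine, (2.0, 2.0, 2.0))
    back = resample_onto(coarse, fine)
    assert back.shape == fine.shape
    assert back.spacing == fine.spacing
    from mpkb.metrics import dsc
    assert dsc(back, fine) > 0.95
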