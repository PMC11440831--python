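"""Body mask, projection, pre-crop, standardization, targets, augmentation."""

import numpy as np
import pytest

import bodycomp as bc
from bodycomp.preprocess import (BACKGROUND_HU, DegenerateInputError,
                                 Provenance, network_pad, row_to_slice_index,
                                 row_to_z_mm, z_mm_to_row)


class TestBodyMask:
    def test_all_air_volume_is_degenerate(self):
        vol = bc.CTVolume(np.full((8, 16, 16), -1000.0), spacing_mm=(3, 3, 3))
        with pytest.raises(DegenerateInputError):
            bc.body_mask(vol)

    def test_mask_covers_trunk(self, noise_free_phantom, noise_free_spec):
        """The whole-body mask is a superset of the constructed trunk,
        including internal air (lungs)."""
        vol, _ = noise_free_phantom
        mask = bc.body_mask(vol)
        trunk = bc.trunk_mask(noise_free_spec)
        assert mask[:, trunk].all()

    def test_detached_artifact_excluded_by_largest_component(self, noise_free_phantom):
        vol, _ = noise_free_phantom
        vox = vol.voxels.copy()
        vox[:, :2, :2] = 500.0  # scanner-table-like object in the corner
        mask = bc.body_mask(bc.CTVolume(vox, vol.spacing_mm))
        assert not mask[:, 0, 0].any()


class TestProjection:
    def test_single_bright_voxel(self):
        vox = np.full((6, 6, 6), -1000.0)
        vox[2, 3, 4] = 1000.0
        vol = bc.CTVolume(vox, spacing_mm=(1, 1, 1))
        proj = bc.coronal_max_projection(vol, np.ones_like(vox, bool))
        assert proj[2, 4] == 1000.0
        assert (proj == -1000.0).sum() == proj.size - 1

    def test_matches_naive_triple_loop(self):
        rng = np.random.default_rng(0)
        vox = rng.uniform(-1000, 1000, (16, 16, 16)).astype(np.float32)
        mask = rng.random((16, 16, 16)) > 0.3
        vol = bc.CTVolume(vox, spacing_mm=(1, 1, 1))
        proj = bc.coronal_max_projection(vol, mask)
        for z in range(16):
            for x in range(16):
                best = BACKGROUND_HU
                for y in range(16):
                    v = vox[z, y, x] if mask[z, y, x] else BACKGROUND_HU
                    best = max(best, v)
                assert proj[z, x] == best

    def test_fully_masked_out_volume_is_background(self):
        vol = bc.CTVolume(np.zeros((4, 4, 4)), spacing_mm=(1, 1, 1))
        proj = bc.coronal_max_projection(vol, np.zeros((4, 4, 4), bool))
        assert (proj == BACKGROUND_HU).all()

    def test_spine_is_bright_in_projection(self, noise_free_phantom):
        vol, gt = noise_free_phantom
        mask = bc.body_mask(vol)
        proj = bc.coronal_max_projection(vol, mask)
        assert proj[gt.l3_slice_index].max() > 150  # vertebral bone dominates


class TestPrecrop:
    def test_far_centroids_trigger_crop(self, phantom):
        vol, gt = phantom
        pre = bc.preprocess.precrop(vol)
        assert pre.cropped
        assert pre.crop_offset_mm > 0
        assert pre.volume.n_slices < vol.n_slices
        # estimated centroids within 10 mm of the construction
        assert abs(pre.lung_centroid_z_mm - gt.meta["lung_centroid_z_mm"]) <= 10
        assert abs(pre.pelvis_centroid_z_mm - gt.meta["pelvis_centroid_z_mm"]) <= 10

    def test_near_centroids_leave_volume_unchanged(self):
        spec = bc.PhantomSpec.desk(seed=55, shape_vox=(100, 96, 96),
                                   n_vertebrae=5, column_start_z_mm=70.0)
        vol, gt = bc.generate_phantom(spec)
        pre = bc.preprocess.precrop(vol)
        assert not pre.cropped
        assert pre.crop_offset_mm == 0.0
        assert pre.volume.n_slices == vol.n_slices
        assert abs(pre.lung_centroid_z_mm - pre.pelvis_centroid_z_mm) <= 200.0

    def test_missing_lung_falls_back_with_warning(self, phantom):
        vol, _ = phantom
        vox = vol.voxels.copy()
        vox[vox < -500] = -90.0  # erase all internal air
        with pytest.warns(UserWarning, match="lung"):
            pre = bc.preprocess.precrop(bc.CTVolume(vox, vol.spacing_mm))
        assert not pre.cropped and pre.crop_offset_mm == 0.0

    def test_l3_survives_the_crop(self, phantom):
        vol, gt = phantom
        pre = bc.preprocess.precrop(vol)
        lo = pre.crop_offset_mm
        hi = lo + pre.volume.n_slices * vol.spacing_mm[0]
        assert lo <= gt.l3_z_mm <= hi


class TestStandardize:
    def test_rescale_to_one_mm_rows_and_pad(self):
        raw = np.full((200, 100), 37.0, dtype=np.float32)
        proj = bc.standardize(raw, spacing_z_mm=2.0)
        assert proj.image.shape == (1064, 512)
        prov = proj.provenance
        assert prov.row_scale == 2.0
        assert prov.pad_top_rows == (1064 - 400) // 2
        assert prov.pad_left_cols == (512 - 100) // 2

    def test_native_grid_input_unchanged_up_to_network_pad(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(-1000, 1000, (1064, 512)).astype(np.float32)
        proj = bc.standardize(raw, spacing_z_mm=1.0)
        assert np.array_equal(proj.image, raw)
        padded = network_pad(proj)
        assert padded.image.shape == (1088, 512)
        assert padded.provenance.pad_top_rows == 12

    def test_padding_is_exact_background(self):
        raw = np.full((100, 50), 123.0, dtype=np.float32)
        proj = bc.standardize(raw, spacing_z_mm=1.0)
        prov = proj.provenance
        assert (proj.image[:prov.pad_top_rows] == BACKGROUND_HU).all()
        assert (proj.image[:, :prov.pad_left_cols] == BACKGROUND_HU).all()

    def test_oversized_input_center_cropped_with_warning(self):
        raw = np.zeros((1200, 600), dtype=np.float32)
        with pytest.warns(UserWarning, match="center-crop"):
            proj = bc.standardize(raw, spacing_z_mm=1.0)
        assert proj.image.shape == (1064, 512)
        assert proj.provenance.pad_top_rows < 0

    def test_marked_row_position_preserved(self):
        """Rescaling keeps the z position of a marked slice within half a row."""
        for dz in (1.0, 2.5, 5.0):
            n = int(400 / dz)
            raw = np.full((n, 32), -1000.0, dtype=np.float32)
            marked = n // 3
            raw[marked] = 500.0
            proj = bc.standardize(raw, spacing_z_mm=dz,
                                  config=bc.StandardizeConfig(row_mm=1.0,
                                                              target_shape=(512, 64),
                                                              network_rows=512))
            row = int(np.argmax(proj.image.max(axis=1)))
            z_est = row_to_z_mm(row, proj.provenance)
            assert abs(z_est - marked * dz) <= 0.5 * max(dz, 1.0)


class TestCoordinateMapping:
    @pytest.mark.parametrize("dz", [1.0, 2.5, 5.0])
    @pytest.mark.parametrize("crop_slices", [0, 15])
    def test_row_slice_round_trip_identity(self, dz, crop_slices):
        # crop offsets are whole numbers of slices by construction
        n = int(round(432 / dz))
        prov = Provenance(crop_offset_mm=crop_slices * dz, spacing_z_mm=dz, row_mm=1.0,
                          pad_top_rows=40, pad_left_cols=0, original_n_slices=n)
        idx = np.arange(crop_slices, crop_slices + n)
        rows = z_mm_to_row(idx * dz, prov)
        assert np.array_equal(row_to_slice_index(rows, prov), idx)

    def test_hand_computed_inverse_example(self):
        prov = Provenance(crop_offset_mm=0.0, spacing_z_mm=2.0, row_mm=1.0,
                          pad_top_rows=12, pad_left_cols=0, original_n_slices=600)
        assert prov.row_scale == 2.0
        assert int(row_to_slice_index(512, prov)) == 250


class TestL3Target:
    def test_interior_band_is_ten_rows(self):
        prov = Provenance(0.0, 1.0, 1.0, 0, 0, 1064)
        mask = bc.make_l3_target(500.0, prov, (1064, 512))
        rows = np.nonzero(mask[:, 0])[0]
        assert rows.tolist() == list(range(496, 506))
        assert mask.sum() == 10 * 512

    def test_border_band_clipped_with_warning(self):
        prov = Provenance(0.0, 1.0, 1.0, 0, 0, 1064)
        with pytest.warns(UserWarning, match="clipped"):
            mask = bc.make_l3_target(2.0, prov, (1064, 512))
        assert np.nonzero(mask[:, 0])[0].tolist() == list(range(0, 8))

    def test_band_scales_with_row_pitch(self):
        prov = Provenance(0.0, 3.0, 2.0, 8, 0, 144)
        mask = bc.make_l3_target(198.5, prov, (256, 96))
        assert mask.sum() == 5 * 96  # 1 cm at 2 mm/row


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(-1000, 200, (1, 64, 64)).astype(np.float32)
        tgt = (rng.random((1, 64, 64)) > 0.8).astype(np.uint8)
        return img, tgt

    def test_zero_config_is_identity(self):
        img, tgt = self._pair()
        cfg = bc.AugmentConfig(rotate_deg=0, scale=0, translate_px=0,
                               elastic_alpha_px=0, arm_probability=0)
        out_i, out_t = bc.augment_batch(img, tgt, cfg, seed=0)
        assert np.array_equal(out_i, img)
        assert np.array_equal(out_t, tgt)

    def test_same_seed_same_batch(self):
        img, tgt = self._pair()
        a = bc.augment_batch(img, tgt, bc.AugmentConfig(), seed=3)
        b = bc.augment_batch(img, tgt, bc.AugmentConfig(), seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_degenerate_ranges_rejected(self):
        img, tgt = self._pair()
        with pytest.raises(ValueError):
            bc.augment_batch(img, tgt, bc.AugmentConfig(scale=1.5), seed=0)

    def test_arm_insertion_outside_body_in_soft_tissue_range(self):
        spec = bc.PhantomSpec.desk(seed=77)
        hu, _ = bc.generate_l3_slice(spec)
        img = hu[None]
        tgt = np.zeros_like(img, dtype=np.uint8)
        cfg = bc.AugmentConfig(rotate_deg=0, scale=0, translate_px=0,
                               elastic_alpha_px=0, arm_probability=1.0)
        out_i, _ = bc.augment_batch(img, tgt, cfg, seed=5)
        changed = out_i[0] != img[0]
        assert changed.sum() > 0
        body = img[0] > cfg.body_threshold_hu
        assert not (changed & body).any()
        assert (out_i[0][changed] >= -29).all() and (out_i[0][changed] <= 150).all()

    def test_geometry_applied_identically_to_image_and_target(self):
        # a bright blob and its target must move together
        img = np.full((1, 64, 64), -1000.0, dtype=np.float32)
        img[0, 20:28, 30:38] = 100.0
        tgt = (img > -500).astype(np.uint8)
        cfg = bc.AugmentConfig(rotate_deg=20, scale=0.1, translate_px=6,
                               elastic_alpha_px=0, arm_probability=0)
        out_i, out_t = bc.augment_batch(img, tgt, cfg, seed=9)
        moved = out_i[0] > -450
        agree = (moved == (out_t[0] > 0)).mean()
        assert agree > 0.98  # interpolation-edge pixels only
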