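"""Patch cropping, normalization, stub extraction, feature maps, WSI tiling."""

import numpy as np
import pytest
from PIL import Image

from hist_st.grid import SpotLayout, map_spots_to_grid
from hist_st.images import (IMAGENET_MEAN, IMAGENET_STD, PatchSpec,
                            StubExtractor, assemble_feature_map,
                            blank_patch_vector, crop_patches,
                            extract_features, prepare_patch,
                            reconstruct_from_tiles, stitch_segment_grids,
                            tile_wsi, tile_wsi_highres)
from tests.conftest import hex_layout


def _one_spot_layout(x, y):
    return SpotLayout(barcodes=["b0"], array_row=[0], array_col=[0],
                      pixel_x=[x], pixel_y=[y], in_tissue=[True])


class TestCropPatches:
    def test_center_crop_mean_equals_local_mean(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, size=(300, 300, 3)).astype(np.uint8)
        patches, bcs = crop_patches(img, _one_spot_layout(150, 150),
                                    PatchSpec(side_px=30))
        assert patches.shape == (1, 30, 30, 3)
        region = img[135:165, 135:165]
        assert patches[0].mean() == pytest.approx(region.mean())

    def test_border_spot_zero_padded(self):
        img = np.full((100, 100, 3), 200, dtype=np.uint8)
        patches, _ = crop_patches(img, _one_spot_layout(2, 2),
                                  PatchSpec(side_px=30))
        assert patches.shape == (1, 30, 30, 3)
        assert (patches[0, :13, :, :] == 0).all()   # rows above the image
        assert (patches[0, :, :13, :] == 0).all()
        assert (patches[0, 14:, 14:, :] == 200).all()

    def test_full_lattice_yields_4992_patches(self, full_visium_layout):
        h = int(full_visium_layout.pixel_y.max() + 20)
        w = int(full_visium_layout.pixel_x.max() + 20)
        img = np.zeros((h, w, 3), dtype=np.uint8)
        patches, _ = crop_patches(img, full_visium_layout, PatchSpec(side_px=8))
        assert len(patches) == 4992

    def test_spot_outside_image_is_an_error_naming_barcodes(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="b0"):
            crop_patches(img, _one_spot_layout(50, 5), PatchSpec(side_px=4))


class TestPreparePatch:
    def test_uniform_patch_at_channel_means_maps_to_zero(self):
        patch = np.broadcast_to(IMAGENET_MEAN * 255.0, (16, 16, 3))
        out = prepare_patch(patch, PatchSpec(side_px=16, resize_to=32))
        np.testing.assert_allclose(out, 0.0, atol=1e-5)

    def test_already_at_target_size_resize_is_identity(self):
        rng = np.random.default_rng(1)
        patch = rng.random((224, 224, 3)) * 255
        out = prepare_patch(patch, PatchSpec(side_px=224, resize_to=224))
        expected = (patch / 255.0 - IMAGENET_MEAN) / IMAGENET_STD
        np.testing.assert_allclose(out, expected.transpose(2, 0, 1), atol=1e-5)

    def test_upscale_matches_pil_bilinear_oracle(self):
        """Independent resampler check: PIL float-mode bilinear on upscales."""
        rng = np.random.default_rng(2)
        patch = (rng.random((30, 30, 3)) * 255).astype(np.float32)
        out = prepare_patch(patch, PatchSpec(side_px=30, resize_to=224))
        for c in range(3):
            ref = np.asarray(Image.fromarray(patch[..., c], mode="F")
                             .resize((224, 224), Image.BILINEAR))
            ref = (ref / 255.0 - IMAGENET_MEAN[c]) / IMAGENET_STD[c]
            np.testing.assert_allclose(out[c], ref, atol=1e-4)

    def test_non_three_channel_rejected(self):
        with pytest.raises(ValueError):
            prepare_patch(np.zeros((8, 8)), PatchSpec())


class TestStubExtractor:
    def test_deterministic_and_duplicate_rows_identical(self):
        rng = np.random.default_rng(3)
        ext = StubExtractor(output_dim=32, seed=0)
        patch = rng.normal(size=(3, 32, 32)).astype(np.float32)
        a, b = ext(patch), ext(patch.copy())
        np.testing.assert_array_equal(a, b)
        assert ext(np.zeros_like(patch)).shape == (32,)

    def test_practically_injective_on_random_patches(self):
        rng = np.random.default_rng(4)
        ext = StubExtractor(output_dim=16, seed=0)
        feats = np.stack([ext(rng.normal(size=(3, 12, 12)).astype(np.float32))
                          for _ in range(1000)])
        # no two of 1,000 random patches collide
        assert len(np.unique(feats.round(5), axis=0)) == 1000

    def test_feature_matrix_shape_contract(self):
        spec = PatchSpec(side_px=6, resize_to=16)
        ext = StubExtractor(output_dim=768, seed=0)
        patches = np.zeros((5, 6, 6, 3), dtype=np.uint8)
        fm = extract_features(patches, [f"b{i}" for i in range(5)], ext, spec)
        assert fm.features.shape == (5, 768)


class TestFeatureMap:
    @pytest.fixture()
    def setup(self):
        lay = hex_layout(6, 8)
        asn = map_spots_to_grid(lay, shape=(6, 8))
        ext = StubExtractor(output_dim=12, seed=0)
        spec = PatchSpec(side_px=7, resize_to=16)
        rng = np.random.default_rng(5)
        patches = (rng.random((len(lay), 7, 7, 3)) * 255).astype(np.uint8)
        fm = extract_features(patches, lay.barcodes, ext, spec)
        blank = blank_patch_vector(ext, spec)
        return lay, asn, fm, blank

    def test_padded_height_and_blank_rows(self, setup):
        lay, asn, fm, blank = setup
        fmap = assemble_feature_map(fm, asn, blank, pad_rows=2)
        assert fmap.values.shape == (12, 8, 8)
        for row in (6, 7):
            np.testing.assert_array_equal(
                fmap.values[:, row, :],
                np.broadcast_to(blank[:, None], (12, 8)))
        assert not fmap.validity[6:].any()

    def test_assigned_cells_reproduce_feature_rows_bitwise(self, setup):
        lay, asn, fm, blank = setup
        fmap = assemble_feature_map(fm, asn, blank, pad_rows=2)
        for i, bc in enumerate(fm.patch_order):
            r, c = asn.cell_of[bc]
            np.testing.assert_array_equal(fmap.values[:, r, c], fm.features[i])

    def test_single_spot_slide_one_nonblank_cell(self):
        lay = SpotLayout(barcodes=["b"], array_row=[0], array_col=[0],
                         pixel_x=[5], pixel_y=[5], in_tissue=[True])
        asn = map_spots_to_grid(lay, shape=(4, 4))
        ext = StubExtractor(output_dim=6, seed=0)
        spec = PatchSpec(side_px=3, resize_to=8)
        fm = extract_features(np.full((1, 3, 3, 3), 90, np.uint8),
                              ["b"], ext, spec)
        blank = blank_patch_vector(ext, spec)
        fmap = assemble_feature_map(fm, asn, blank, pad_rows=2)
        nonblank = (fmap.values != blank[:, None, None]).any(axis=0)
        assert nonblank.sum() == 1

    def test_unknown_barcode_rejected(self, setup):
        lay, asn, fm, blank = setup
        fm.patch_order[0] = "stranger"
        with pytest.raises(KeyError):
            assemble_feature_map(fm, asn, blank)


class TestTileWsi:
    def test_exactly_divisible_image(self):
        img = np.zeros((800, 640, 3), dtype=np.uint8)
        patches, man = tile_wsi(img)
        assert patches.shape == (5120, 10, 10, 3)
        assert man["patch_side"] == 10
        assert man["pad_top"] == 0 and man["pad_left"] == 0

    def test_non_divisible_image_follows_ceil_rule(self):
        img = np.zeros((1000, 700, 3), dtype=np.uint8)
        patches, man = tile_wsi(img)
        assert man["patch_side"] == 13          # ceil(max(1000/80, 700/64))
        assert patches.shape == (5120, 13, 13, 3)
        # canvas 1040 x 832 recorded via manifest geometry
        assert 80 * man["patch_side"] == 1040
        assert 64 * man["patch_side"] == 832

    @pytest.mark.parametrize("shape", [(123, 456), (64, 80), (2000, 100)])
    def test_any_input_gives_5120_patches(self, shape):
        img = np.zeros((*shape, 3), dtype=np.uint8)
        patches, _ = tile_wsi(img)
        assert patches.shape[0] == 5120

    def test_manifest_allows_exact_reconstruction(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 255, size=(170, 130, 3)).astype(np.uint8)
        patches, man = tile_wsi(img)
        canvas = reconstruct_from_tiles(patches, man)
        t, l = man["pad_top"], man["pad_left"]
        np.testing.assert_array_equal(canvas[t:t + 170, l:l + 130], img)
        # padding is blank (white)
        assert (canvas[:t] == 255).all()


class TestTileWsiHighres:
    def test_n1_identical_to_plain_tiling(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 255, size=(160, 128, 3)).astype(np.uint8)
        plain, man = tile_wsi(img)
        blocks = tile_wsi_highres(img, 1)
        assert len(blocks) == 1
        np.testing.assert_array_equal(blocks[0]["patches"], plain)

    def test_n2_geometry(self):
        img = np.zeros((160, 128, 3), dtype=np.uint8)
        blocks = tile_wsi_highres(img, 2)
        assert len(blocks) == 4
        stitched = stitch_segment_grids(
            {b["block"]: np.zeros((3, 80, 64)) for b in blocks}, 2)
        assert stitched.shape == (3, 160, 128)

    def test_stitching_places_blocks_at_offsets(self):
        grids = {(i, j): np.full((1, 80, 64), 10 * i + j) for i in range(2)
                 for j in range(2)}
        out = stitch_segment_grids(grids, 2)
        assert (out[0, :80, :64] == 0).all()
        assert (out[0, :80, 64:] == 1).all()
        assert (out[0, 80:, :64] == 10).all()
        assert (out[0, 80:, 64:] == 11).all()
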