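"""Tissue segmentation, tessellation geometry, and the toy featurizer."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from histomil.synthdata import generate_synthetic_slide
from histomil.wsiprep import (SlideImage, Tile, TissueMask, augment_stain,
                              segment_tissue, tessellate, toy_featurize)


def _textured_patch_slide(rng, size=256, patch=64, blur=False):
    """White canvas with one high-contrast textured square patch."""
    img = np.full((size, size, 3), 255, dtype=np.uint8)
    r0 = c0 = (size - patch) // 2
    tex = rng.integers(40, 200, size=(patch, patch, 3)).astype(np.float64)
    img[r0:r0 + patch, c0:c0 + patch] = tex.astype(np.uint8)
    if blur:
        # blur the composite so the patch boundary is soft too: edge
        # density drops below threshold across the whole patch
        img = gaussian_filter(img.astype(np.float64), sigma=(12, 12, 0))
        img = np.clip(img, 0, 255).astype(np.uint8)
    truth = np.zeros((size, size), dtype=bool)
    truth[r0:r0 + patch, c0:c0 + patch] = True
    return SlideImage(pixels=img, mpp=0.5), truth


class TestSegmentTissue:
    def test_all_white_gives_empty_mask(self):
        slide = SlideImage(np.full((256, 256, 3), 255, dtype=np.uint8), 0.5)
        assert segment_tissue(slide).mask.sum() == 0

    def test_textured_patch_recovered(self, rng):
        slide, truth = _textured_patch_slide(rng)
        mask = segment_tissue(slide).mask
        recall = mask[truth].mean()
        spurious = mask[~truth].mean()
        assert recall > 0.9
        assert spurious < 0.05

    def test_blurred_patch_rejected(self, rng):
        slide, truth = _textured_patch_slide(rng, blur=True)
        mask = segment_tissue(slide).mask
        assert mask[truth].mean() < 0.2

    def test_invariant_to_white_border_padding(self, rng):
        slide, _ = _textured_patch_slide(rng)
        pad = 32
        padded = np.full((256 + 2 * pad, 256 + 2 * pad, 3), 255,
                         dtype=np.uint8)
        padded[pad:-pad, pad:-pad] = slide.pixels
        m1 = segment_tissue(slide).mask
        m2 = segment_tissue(SlideImage(padded, 0.5)).mask
        np.testing.assert_array_equal(m2[pad:-pad, pad:-pad], m1)
        assert m2[:pad].sum() == 0

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            SlideImage(np.zeros((10, 10), dtype=np.uint8), 0.5)

    def test_synthetic_slide_dice(self):
        slide, truth = generate_synthetic_slide(512, 512, n_blobs=1, seed=3)
        mask = segment_tissue(slide).mask
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.9


class TestTessellate:
    def _full(self, size, mpp):
        slide = SlideImage(
            np.random.default_rng(0).integers(
                60, 200, size=(size, size, 3)).astype(np.uint8), mpp)
        return slide, TissueMask(np.ones((size, size), dtype=bool))

    def test_grid_at_native_resolution(self):
        slide, mask = self._full(2048, 0.5)
        tiles = tessellate(slide, mask, tile_size_px=512, target_mpp=0.5,
                           min_tissue_fraction=0.5)
        assert len(tiles) == 16
        assert sorted(t.coord for t in tiles) == [
            (c, r) for c in range(4) for r in range(4)]
        assert all(t.pixels.shape == (512, 512, 3) for t in tiles)

    def test_higher_magnification_rescaled(self):
        # 0.25 mpp source is downscaled 2x before gridding
        slide, mask = self._full(2048, 0.25)
        tiles = tessellate(slide, mask, tile_size_px=512, target_mpp=0.5,
                           min_tissue_fraction=0.5)
        assert len(tiles) == 4

    def test_edge_remainder_dropped(self):
        slide, mask = self._full(600, 0.5)
        tiles = tessellate(slide, mask, tile_size_px=512, target_mpp=0.5,
                           min_tissue_fraction=0.5)
        assert len(tiles) == 1
        assert tiles[0].coord == (0, 0)

    def test_empty_mask_yields_no_tiles(self):
        slide, _ = self._full(1024, 0.5)
        mask = TissueMask(np.zeros((1024, 1024), dtype=bool))
        assert tessellate(slide, mask, 512, 0.5, 0.5) == []

    def test_invalid_target_mpp(self):
        slide, mask = self._full(512, 0.5)
        with pytest.raises(ValueError):
            tessellate(slide, mask, 512, 0.0, 0.5)

    def test_tile_count_monotone_in_min_tissue_fraction(self, rng):
        size = 1024
        img = rng.integers(0, 255, size=(size, size, 3)).astype(np.uint8)
        mask = TissueMask(rng.random((size, size)) < 0.55)
        slide = SlideImage(img, 0.5)
        counts = [len(tessellate(slide, mask, 256, 0.5, f))
                  for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_tiles_within_bounds_and_disjoint(self, rng):
        slide, mask = self._full(1100, 0.5)
        tiles = tessellate(slide, mask, 256, 0.5, 0.5)
        seen = set()
        for t in tiles:
            assert t.coord not in seen
            seen.add(t.coord)
            c, r = t.coord
            assert (c + 1) * 256 <= 1100 and (r + 1) * 256 <= 1100


class TestToyFeaturizer:
    def _tiles(self, rng, n=3, side=32):
        return [Tile(pixels=rng.integers(0, 255, size=(side, side, 3))
                     .astype(np.uint8), coord=(i, 0), tissue_fraction=1.0)
                for i in range(n)]

    def test_identical_tiles_identical_rows(self, rng):
        t = self._tiles(rng, n=1)[0]
        twin = Tile(pixels=t.pixels.copy(), coord=(5, 5),
                    tissue_fraction=1.0)
        emb = toy_featurize([t, twin], seed=0, output_dim=32)
        np.testing.assert_array_equal(emb[0], emb[1])

    def test_same_seed_reproducible(self, rng):
        tiles = self._tiles(rng)
        e1 = toy_featurize(tiles, seed=4, output_dim=64)
        e2 = toy_featurize(tiles, seed=4, output_dim=64)
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape == (3, 64)

    def test_darkened_tile_moves_embedding(self, rng):
        t = self._tiles(rng, n=1)[0]
        dark = Tile(pixels=(t.pixels * 0.5).astype(np.uint8), coord=(0, 0),
                    tissue_fraction=1.0)
        emb = toy_featurize([t, dark], seed=0, output_dim=32)
        assert np.linalg.norm(emb[0] - emb[1]) > 0


class TestAugmentStain:
    def test_default_identity(self, rng):
        tiles = [Tile(pixels=rng.integers(0, 255, size=(16, 16, 3))
                      .astype(np.uint8), coord=(0, 0), tissue_fraction=1.0)]
        out = augment_stain(tiles)
        np.testing.assert_array_equal(out[0].pixels, tiles[0].pixels)

    def test_flip_hook_preserves_contract(self, rng):
        tiles = [Tile(pixels=rng.integers(0, 255, size=(16, 16, 3))
                      .astype(np.uint8), coord=(i, 0), tissue_fraction=1.0)
                 for i in range(4)]

        def flip(ts):
            return [Tile(pixels=t.pixels[:, ::-1], coord=t.coord,
                         tissue_fraction=t.tissue_fraction) for t in ts]

        out = augment_stain(tiles, flip)
        assert len(out) == 4
        np.testing.assert_array_equal(out[0].pixels,
                                      tiles[0].pixels[:, ::-1])

    def test_count_changing_hook_rejected(self, rng):
        tiles = [Tile(pixels=rng.integers(0, 255, size=(8, 8, 3))
                      .astype(np.uint8), coord=(0, 0), tissue_fraction=1.0)]
        with pytest.raises(ValueError):
            augment_stain(tiles, lambda ts: [])
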