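"""Slide preprocessing: tissue segmentation, tessellation into tiles, and
the pluggable tile-embedding interface.

Tissue is found by combining an RGB background threshold (near-white
pixels are background) with a local Canny edge-density criterion that
rejects blurry, texture-free regions; the surviving mask is closed
morphologically. The slide is then rescaled to the working resolution
(0.5 microns per pixel, i.e. 20x) and cut into a non-overlapping grid of
512 x 512 pixel tiles; tiles with too little tissue and partial edge
tiles are dropped. Every retained tile enters the bag regardless of
tumor content — no manual annotation is used.

The production feature extractor (a pretrained histology transformer) is
deliberately behind the :class:`EmbeddingProvider` interface; the
deterministic :class:`ToyFeaturizer` provided here maps channel
histograms and texture summaries through a fixed random projection and
exists so the whole pipeline can run and be tested without pretrained
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage import feature, morphology, transform

__all__ = [
    "SlideImage",
    "TissueMask",
    "Tile",
    "EmbeddingProvider",
    "ToyFeaturizer",
    "segment_tissue",
    "tessellate",
    "toy_featurize",
    "augment_stain",
]


@dataclass
class SlideImage:
    """An 8-bit RGB raster image with a known physical resolution."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: float          # microns per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("slide must be an H x W x 3 RGB array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("slide must be 8-bit RGB")
        if not np.isfinite(self.mpp) or self.mpp <= 0:
            raise ValueError("mpp must be finite and positive")


@dataclass
class TissueMask:
    mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class Tile:
    pixels: np.ndarray         # (side, side, 3) uint8
    coord: tuple[int, int]     # (col, row) in tile units, origin top-left
    tissue_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must be in [0, 1]")


class EmbeddingProvider(Protocol):
    """Black-box tile-batch embedder (the production model plugs in here)."""

    name: str
    output_dim: int

    def embed(self, tiles: Sequence[Tile]) -> np.ndarray: ...


def segment_tissue(slide: SlideImage, rgb_threshold: int = 224,
                   canny_low: int = 40, canny_high: int = 100,
                   min_edge_density: float = 0.02,
                   edge_window: int = 64,
                   closing_radius: int = 8) -> TissueMask:
    """Segment tissue via RGB thresholding plus Canny edge density.

    A pixel is background when all three channels exceed `rgb_threshold`
    (near-white). Of the remaining pixels, only those whose local Canny
    edge density (mean edge fraction in an `edge_window`-sided square)
    reaches `min_edge_density` are kept, which rejects blurry and
    texture-free regions. Morphological closing fills small holes.
    """
    px = slide.pixels
    not_background = ~np.all(px > rgb_threshold, axis=2)
    gray = px.mean(axis=2) / 255.0
    edges = feature.canny(gray, sigma=1.0,
                          low_threshold=canny_low / 255.0,
                          high_threshold=canny_high / 255.0)
    # mode="constant" so that pure-white (edge-free) padding outside the
    # image never changes the density inside it
    density = ndimage.uniform_filter(edges.astype(np.float64),
                                     size=edge_window, mode="constant")
    mask = not_background & (density >= min_edge_density)
    if closing_radius > 0:
        mask = morphology.closing(
            mask, morphology.footprint_rectangle(
                (2 * closing_radius + 1, 2 * closing_radius + 1)))
        mask &= not_background
    return TissueMask(mask)


def tessellate(slide: SlideImage, mask: TissueMask,
               tile_size_px: int = 512, target_mpp: float = 0.5,
               min_tissue_fraction: float = 0.5) -> list[Tile]:
    """Cut the slide into a non-overlapping grid of square tiles.

    The slide is first rescaled by slide.mpp / target_mpp so every tile
    covers the same physical area; partial tiles at the right/bottom edge
    are dropped, as are tiles whose tissue fraction (mask mean) is below
    `min_tissue_fraction`. An empty mask yields an empty list.
    """
    if target_mpp <= 0:
        raise ValueError("target_mpp must be positive")
    if mask.mask.shape != slide.pixels.shape[:2]:
        raise ValueError("mask not aligned with slide")
    scale = slide.mpp / target_mpp
    px = slide.pixels
    m = mask.mask
    if not np.isclose(scale, 1.0):
        new_shape = (max(1, int(round(px.shape[0] * scale))),
                     max(1, int(round(px.shape[1] * scale))))
        px = transform.resize(px, new_shape + (3,), order=1,
                              preserve_range=True,
                              anti_aliasing=scale < 1.0).astype(np.uint8)
        m = transform.resize(m.astype(np.float64), new_shape, order=0,
                             preserve_range=True, anti_aliasing=False) > 0.5
    h, w = px.shape[:2]
    tiles: list[Tile] = []
    for row in range(h // tile_size_px):
        for col in range(w // tile_size_px):
            r0, c0 = row * tile_size_px, col * tile_size_px
            frac = float(m[r0:r0 + tile_size_px, c0:c0 + tile_size_px].mean())
            if frac < min_tissue_fraction:
                continue
            tiles.append(Tile(
                pixels=px[r0:r0 + tile_size_px, c0:c0 + tile_size_px].copy(),
                coord=(col, row),
                tissue_fraction=frac,
            ))
    return tiles


def _tile_features(tile: Tile) -> np.ndarray:
    """Hand-crafted per-tile summary: channel histograms, channel moments,
    gradient-magnitude histogram."""
    px = tile.pixels.astype(np.float64) / 255.0
    feats: list[np.ndarray] = []
    for c in range(3):
        hist, _ = np.histogram(px[:, :, c], bins=8, range=(0.0, 1.0))
        feats.append(hist / hist.sum())
        feats.append(np.array([px[:, :, c].mean(), px[:, :, c].std()]))
    gray = px.mean(axis=2)
    gy, gx = np.gradient(gray)
    gmag = np.hypot(gx, gy)
    ghist, _ = np.histogram(gmag, bins=8, range=(0.0, 0.5))
    feats.append(ghist / max(1, ghist.sum()))
    feats.append(np.array([gmag.mean(), gmag.std()]))
    return np.concatenate(feats)  # 40 features


class ToyFeaturizer:
    """Deterministic stand-in embedder: fixed-seed random projection of
    hand-crafted tile statistics to `output_dim` dimensions."""

    def __init__(self, seed: int = 0, output_dim: int = 768):
        self.name = f"toy-v1-seed{seed}"
        self.output_dim = output_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._projection = rng.normal(size=(40, output_dim)) / np.sqrt(40)

    def embed(self, tiles: Sequence[Tile]) -> np.ndarray:
        if len(tiles) == 0:
            raise ValueError("no tiles to embed")
        feats = np.stack([_tile_features(t) for t in tiles])
        return np.tanh(feats @ self._projection).astype(np.float32)


def toy_featurize(tiles: Sequence[Tile], seed: int = 0,
                  output_dim: int = 768) -> np.ndarray:
    """Embed tiles with the deterministic toy featurizer; identical tiles
    give identical rows and reruns with the same seed are bit-identical."""
    return ToyFeaturizer(seed=seed, output_dim=output_dim).embed(tiles)


def augment_stain(tiles: Sequence[Tile],
                  hook: Callable[[Sequence[Tile]], Sequence[Tile]] | None
                  = None) -> list[Tile]:
    """Stain-augmentation hook point.

    The default hook is the identity; a user-supplied augmenter (e.g. a
    stain-transfer model) may replace it but must preserve tile count and
    pixel shapes.
    """
    if hook is None:
        return list(tiles)
    out = list(hook(tiles))
    if len(out) != len(tiles):
        raise ValueError("augmentation hook changed the tile count")
    for a, b in zip(tiles, out):
        if a.pixels.shape != b.pixels.shape:
            raise ValueError("augmentation hook changed a tile's shape")
    return out
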