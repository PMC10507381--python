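"""Explainability: attention rollout, per-head class-token attention,
patch-wise classification scores, and heatmap rendering.

Attention rollout attributes the class token's final state to the input
tiles by multiplying the layers' attention matrices recursively. Within
each layer the heads are averaged, the identity is mixed in for the
residual path (0.5 * head-mean + 0.5 * I by default), and rows are
re-normalized so every intermediate matrix stays row-stochastic. The
class-token row of the product, restricted to tile positions, is the raw
rollout map. For display, values are clamped to the lower/upper 5%
quantiles and min-max rescaled to [0, 1]; patch-wise classification
scores are probabilities already in [0, 1] and are rendered unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import colormaps
from PIL import Image

from .aggregator import AttentionRecord, TransformerAggregator

__all__ = [
    "RolloutMap",
    "PatchScoreMap",
    "attention_rollout",
    "head_attention_maps",
    "normalize_for_display",
    "patch_scores",
    "render_heatmap",
]


@dataclass
class RolloutMap:
    """Per-tile contribution of each tile to the class-token output."""

    raw: np.ndarray       # length n, non-negative
    display: np.ndarray   # length n, quantile-clamped to [0, 1]
    class_token: int = 0


@dataclass
class PatchScoreMap:
    """Per-tile classification probability (already in [0, 1])."""

    scores: np.ndarray


def _rollout_factor(layer: np.ndarray, with_identity: bool) -> np.ndarray:
    """Head-mean attention, residual-adjusted and row-renormalized."""
    A = layer.mean(axis=0)
    if with_identity:
        A = 0.5 * A + 0.5 * np.eye(A.shape[0])
    return A / A.sum(axis=1, keepdims=True)


def attention_rollout(record: AttentionRecord, class_token: int = 0,
                      with_identity: bool = True,
                      clamp_quantile: float = 0.05) -> RolloutMap:
    """Roll attention out across layers and read off the class-token row.

    rollout = A~_L @ ... @ A~_1 with A~ the residual-adjusted head-mean
    of each layer; entries of the class-token row at tile positions form
    the raw map.
    """
    if record.n_layers == 0:
        raise ValueError("empty attention record")
    m = record.layers[0].shape[-1]
    for layer in record.layers:
        if layer.shape[-2:] != (m, m):
            raise ValueError("mismatched attention shapes across layers")
    t = record.n_class_tokens
    if not 0 <= class_token < max(t, 1):
        raise ValueError(f"class_token must be in 0..{t - 1}")
    rollout = _rollout_factor(record.layers[0], with_identity)
    for layer in record.layers[1:]:
        rollout = _rollout_factor(layer, with_identity) @ rollout
    raw = rollout[class_token, t:].copy()
    return RolloutMap(raw=raw,
                      display=normalize_for_display(raw, q=clamp_quantile),
                      class_token=class_token)


def head_attention_maps(record: AttentionRecord,
                        class_token: int = 0) -> np.ndarray:
    """Class-token attention over tiles for every (layer, head).

    Returns an array of shape (n_layers, n_heads, n): the post-softmax
    query-key row of the class token, restricted to tile positions
    (16 maps for the default 2-layer, 8-head model).
    """
    t = record.n_class_tokens
    if t < 1:
        raise ValueError("head maps require a class-token model")
    return np.stack([layer[:, class_token, t:] for layer in record.layers])


def normalize_for_display(values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Clamp to the [q, 1-q] empirical quantiles, then rescale to [0, 1].

    A constant input maps to all 0.5 by convention.
    """
    values = np.asarray(values, dtype=np.float64)
    if not 0.0 <= q < 0.5:
        raise ValueError("q must be in [0, 0.5)")
    lo = np.quantile(values, q)
    hi = np.quantile(values, 1.0 - q)
    if hi <= lo:
        return np.full_like(values, 0.5)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def patch_scores(bag, model: TransformerAggregator,
                 class_token: int = 0) -> PatchScoreMap:
    """Feed each tile through the model as a singleton bag and collect
    the classification probabilities (visualized without clamping)."""
    x = bag.embeddings if hasattr(bag, "embeddings") else np.asarray(bag)
    scores = np.array([
        float(model.predict(x[i:i + 1]).probabilities[class_token])
        for i in range(x.shape[0])])
    return PatchScoreMap(scores=scores)


def render_heatmap(map_values: np.ndarray, coords: np.ndarray,
                   tile_size_px: int = 512, out_png=None, out_csv=None,
                   base_image: np.ndarray | None = None,
                   cmap: str = "viridis", alpha: float = 0.6,
                   cell_px: int = 8,
                   raw_values: np.ndarray | None = None) -> np.ndarray:
    """Paint per-tile values onto the slide's tile grid.

    Values (in [0, 1]; yellow = high contribution, purple = low with the
    default colormap) are painted at `cell_px` pixels per tile, optionally
    alpha-blended over a slide thumbnail. Writes a PNG and a per-tile CSV
    (col, row, raw, display) when paths are given; returns the RGB array.
    """
    map_values = np.asarray(map_values, dtype=np.float64)
    coords = np.asarray(coords, dtype=np.int64)
    if coords.shape != (map_values.size, 2):
        raise ValueError("coords must have shape n x 2 matching values")
    if (coords < 0).any():
        raise ValueError("negative tile coordinates")
    n_cols = int(coords[:, 0].max()) + 1
    n_rows = int(coords[:, 1].max()) + 1
    grid = np.full((n_rows, n_cols), np.nan)
    grid[coords[:, 1], coords[:, 0]] = map_values
    colored = colormaps[cmap](np.nan_to_num(grid, nan=0.0))[:, :, :3]
    colored[np.isnan(grid)] = 1.0  # empty cells rendered white
    img = np.repeat(np.repeat(colored, cell_px, axis=0), cell_px, axis=1)
    if base_image is not None:
        from skimage import transform
        thumb = transform.resize(base_image, img.shape[:2] + (3,), order=1,
                                 preserve_range=True) / 255.0
        has_value = np.repeat(np.repeat(~np.isnan(grid), cell_px, axis=0),
                              cell_px, axis=1)[:, :, None]
        img = np.where(has_value, alpha * img + (1 - alpha) * thumb, thumb)
    rgb = (np.clip(img, 0, 1) * 255).astype(np.uint8)
    if out_png is not None:
        Image.fromarray(rgb).save(Path(out_png), format="PNG")
    if out_csv is not None:
        pd.DataFrame({
            "col": coords[:, 0], "row": coords[:, 1],
            "raw": (np.asarray(raw_values, dtype=np.float64)
                    if raw_values is not None else map_values),
            "display": map_values,
        }).to_csv(out_csv, index=False)
    return rgb
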