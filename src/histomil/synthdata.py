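"""Synthetic data emulating the statistical structure the MIL pipeline
assumes, so every stage can be exercised without any slide downloads.

Embedding bags follow the standard multiple-instance generative model:
a bag is positive iff it contains at least one *witness* tile. Background
tiles are isotropic Gaussian noise N(0, sigma^2 I); in positive bags a
fraction w of tiles is shifted by delta along a fixed unit direction u
(the "witness direction"), mimicking the focal morphology that carries a
biomarker signal. The default background scale (sigma = 0.3, i.e. a
witness shift of five background standard deviations at the default
delta = 1.5) places the benchmark in the regime the MIL assumption
describes: witness tiles are individually recognizable, as the
label-defining morphology is to a pathologist, and the difficulty lies
in aggregation under weak supervision, not in per-tile detection.
Per-cohort mean offsets model scanner/site shifts, and
:func:`generate_external_cohort` adds a global offset of chosen magnitude
to emulate an out-of-domain cohort.

Defaults mirror the clinical setting being emulated: positive-class
prevalence 12.9%, embedding dimension 768, and a long-tailed bag-size
distribution (log-normal, median 2000, capped at 12000 tiles per
patient). `SynthBagConfig.test_scale()` is the scaled-down profile used
throughout the test suite (200 patients, bag sizes 50-300, d_in 64).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .bagio import BagStore, CohortManifest, TileBag

__all__ = [
    "SynthBagConfig",
    "generate_bags",
    "generate_external_cohort",
    "generate_synthetic_slide",
    "bags_to_store",
]


@dataclass
class SynthBagConfig:
    n_patients: int = 200
    prevalence: float = 0.129
    bag_size_median: int = 2000
    bag_size_sigma: float = 0.6     # log-space spread of the log-normal
    bag_size_min: int = 50
    bag_size_cap: int = 12000
    d_in: int = 768
    witness_fraction: float = 0.05
    effect_size: float = 1.5        # witness mean shift along u, in sigmas
    noise_sigma: float = 0.3
    cohort: str = "SYNTH"
    cohort_offsets: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.bag_size_cap < 1:
            raise ValueError("bag_size_cap must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.witness_fraction <= 1.0:
            raise ValueError("witness_fraction must be in (0, 1]")

    @classmethod
    def test_scale(cls, **overrides) -> "SynthBagConfig":
        """Scaled-down profile for desk-scale experiments."""
        base = dict(n_patients=200, bag_size_median=120, bag_size_sigma=0.4,
                    bag_size_min=50, bag_size_cap=300, d_in=64)
        base.update(overrides)
        return cls(**base)


def _witness_direction(cfg: SynthBagConfig) -> np.ndarray:
    """Fixed unit direction carrying the label signal; depends only on
    d_in so that external cohorts generated from a derived config share
    the same signal subspace."""
    rng = np.random.default_rng(987654321 + cfg.d_in)
    u = rng.normal(size=cfg.d_in)
    return u / np.linalg.norm(u)


def generate_bags(
        cfg: SynthBagConfig,
        global_offset: np.ndarray | None = None,
) -> tuple[list[TileBag], CohortManifest]:
    """Draw a cohort of planted-witness bags.

    Each patient gets label ~ Bernoulli(prevalence) and a bag of
    log-normal size. Positive bags contain round(w * n) witness tiles
    (at least one) drawn N(delta * u, sigma^2 I); all other tiles are
    N(0, sigma^2 I), plus any cohort offset. The per-tile witness mask is
    stored on each bag as ground truth for explainability checks.
    Fully deterministic given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    u = _witness_direction(cfg)
    offset = np.zeros(cfg.d_in)
    if cfg.cohort in cfg.cohort_offsets:
        off_dir_rng = np.random.default_rng(
            123456789 + cfg.d_in + len(cfg.cohort))
        v = off_dir_rng.normal(size=cfg.d_in)
        offset = offset + cfg.cohort_offsets[cfg.cohort] * v / np.linalg.norm(v)
    if global_offset is not None:
        offset = offset + global_offset

    bags: list[TileBag] = []
    rows = []
    width = len(str(cfg.n_patients))
    for i in range(cfg.n_patients):
        pid = f"P{i:0{width}d}"
        label = int(rng.random() < cfg.prevalence)
        n = int(np.clip(
            round(cfg.bag_size_median
                  * np.exp(rng.normal(0.0, cfg.bag_size_sigma))),
            cfg.bag_size_min, cfg.bag_size_cap))
        emb = rng.normal(0.0, cfg.noise_sigma, size=(n, cfg.d_in))
        witness = np.zeros(n, dtype=bool)
        if label == 1:
            n_w = max(1, int(round(cfg.witness_fraction * n)))
            idx = rng.choice(n, size=n_w, replace=False)
            emb[idx] += cfg.effect_size * u
            witness[idx] = True
        emb += offset
        side = int(np.ceil(np.sqrt(n)))
        grid = np.arange(n)
        coords = np.stack([grid % side, grid // side], axis=1)
        slide_id = f"{pid}_S0"
        bags.append(TileBag(
            embeddings=emb.astype(np.float32), coords=coords,
            patient_id=pid, slide_ids=[slide_id], mpp=0.5,
            tile_size_px=512, featurizer="synthetic-witness",
            witness_mask=witness,
        ))
        rows.append({"patient_id": pid,
                     "slide_refs": [f"{slide_id}.png"],
                     "label": label, "cohort": cfg.cohort})
    manifest = CohortManifest(pd.DataFrame(rows))
    return bags, manifest


def generate_external_cohort(
        cfg: SynthBagConfig, shift_magnitude: float,
        cohort: str | None = None, seed: int | None = None,
) -> tuple[list[TileBag], CohortManifest]:
    """Cohort with the same witness structure but all tiles offset by a
    fixed vector of the given magnitude (a site/scanner domain shift)."""
    ext = replace(cfg,
                  cohort=cohort or f"{cfg.cohort}-EXT",
                  seed=cfg.seed if seed is None else seed)
    offset = np.zeros(cfg.d_in)
    if shift_magnitude != 0.0:
        dir_rng = np.random.default_rng(555000111 + cfg.d_in)
        v = dir_rng.normal(size=cfg.d_in)
        offset = shift_magnitude * v / np.linalg.norm(v)
    return generate_bags(ext, global_offset=offset)


def bags_to_store(bags, store: BagStore, overwrite: bool = False) -> None:
    """Write a list of single-slide bags into a BagStore."""
    for bag in bags:
        store.write(bag, overwrite=overwrite)


def generate_synthetic_slide(
        width: int = 2048, height: int = 2048, n_blobs: int = 3,
        blur_region: bool = False, seed: int = 0, mpp: float = 0.5,
):
    """Render a toy H&E-like slide: white canvas with textured pink/purple
    elliptical tissue blobs, optionally with one Gaussian-blurred region.

    Returns (SlideImage, ground-truth tissue mask). The mask marks the
    sharp (non-blurred) blob area, which is what tissue segmentation
    should recover.
    """
    from scipy.ndimage import gaussian_filter

    from .wsiprep import SlideImage

    rng = np.random.default_rng(seed)
    img = np.full((height, width, 3), 255.0)
    mask = np.zeros((height, width), dtype=bool)
    yy, xx = np.mgrid[0:height, 0:width]
    for _ in range(n_blobs):
        cy = rng.uniform(0.2, 0.8) * height
        cx = rng.uniform(0.2, 0.8) * width
        ry = rng.uniform(0.08, 0.2) * height
        rx = rng.uniform(0.08, 0.2) * width
        blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        # eosin-pink base with hematoxylin-purple speckle texture
        base = np.array([rng.uniform(190, 230), rng.uniform(120, 160),
                         rng.uniform(170, 210)])
        texture = rng.normal(0.0, 35.0, size=(height, width, 3))
        nuclei = rng.random((height, width)) < 0.03
        for c, drop in enumerate((110.0, 120.0, 60.0)):
            channel = img[:, :, c]
            channel[blob] = base[c] + texture[:, :, c][blob]
            channel[blob & nuclei] = base[c] - drop
        mask |= blob
    img = np.clip(img, 0, 255)
    blur_mask = np.zeros_like(mask)
    if blur_region and mask.any():
        # heavily blur the left half of the tissue area (an out-of-focus
        # scan region); the transition is feathered so the defect has no
        # sharp internal boundary, as in a real focal-plane failure
        cols = np.where(mask.any(axis=0))[0]
        mid = cols[len(cols) // 2]
        blur_mask = mask & (xx <= mid)
        weight = gaussian_filter(blur_mask.astype(np.float64), sigma=16)
        weight = np.clip(weight * 1.5, 0.0, 1.0)[:, :, None]
        blurred = gaussian_filter(img, sigma=(12, 12, 0))
        img = weight * blurred + (1.0 - weight) * img
        mask = mask & ~blur_mask
    slide = SlideImage(pixels=img.astype(np.uint8), mpp=mpp)
    return slide, mask
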