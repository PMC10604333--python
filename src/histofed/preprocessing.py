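"""Tiling of raster images into fixed-size patches with a tissue filter.

Slides are cut into non-overlapping 224 x 224 tiles (row-major, 0-based,
half-open pixel intervals); a tile is kept only if at least 70% of its
pixels look like tissue.  Tissue detection is luminance thresholding by
default (background on an H&E slide is near-white), with Otsu's method as an
option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import PatchImage


@dataclass
class TilingConfig:
    patch_size: int = 224
    stride: int = 224  # == patch_size: non-overlapping
    min_tissue_fraction: float = 0.70
    background_luminance_threshold: float = 0.90
    tissue_detector: str = "luminance"  # or "otsu"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must lie in (0, 1]")
        if self.stride < 1 or self.patch_size < 1:
            raise ValueError("stride and patch_size must be >= 1")
        if self.tissue_detector not in ("luminance", "otsu"):
            raise ValueError(f"unknown tissue detector {self.tissue_detector!r}")


def tissue_fraction(image: np.ndarray, threshold: float = 0.90) -> float:
    """Fraction of pixels whose mean-channel luminance is below threshold."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    lum = image.mean(axis=-1) if image.ndim == 3 else image
    return float(np.mean(lum < threshold))


def _otsu_threshold(image: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    lum = np.asarray(image, dtype=np.float64).mean(axis=-1)
    return float(threshold_otsu(lum))


def extract_patches(
    image: np.ndarray,
    cfg: TilingConfig | None = None,
    label: int | None = None,
    magnification: int | None = None,
    slide_id: str = "slide",
    client_id: str = "",
) -> list[PatchImage]:
    """Cut an RGB raster into tiles and keep those passing the tissue filter.

    Partial border tiles are dropped; patch ids encode the 0-based half-open
    pixel interval of each tile's origin.  An image smaller than one patch
    yields an empty list with a warning.
    """
    cfg = cfg or TilingConfig()
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    ps = cfg.patch_size
    if h < ps or w < ps:
        warnings.warn(
            f"image {h}x{w} smaller than patch size {ps}; no tiles extracted",
            stacklevel=2,
        )
        return []
    thr = (
        _otsu_threshold(image)
        if cfg.tissue_detector == "otsu"
        else cfg.background_luminance_threshold
    )
    patches = []
    for r0 in range(0, h - ps + 1, cfg.stride):
        for c0 in range(0, w - ps + 1, cfg.stride):
            tile = image[r0 : r0 + ps, c0 : c0 + ps]
            if tissue_fraction(tile, thr) < cfg.min_tissue_fraction:
                continue
            patches.append(
                PatchImage(
                    pixels=tile,
                    patch_id=f"{slide_id}_r{r0}-{r0 + ps}_c{c0}-{c0 + ps}",
                    label=label,
                    magnification=magnification,
                    client_id=client_id,
                    slide_id=slide_id,
                )
            )
    return patches


def candidate_tile_count(h: int, w: int, cfg: TilingConfig | None = None) -> int:
    cfg = cfg or TilingConfig()
    if h < cfg.patch_size or w < cfg.patch_size:
        return 0
    return (1 + (h - cfg.patch_size) // cfg.stride) * (
        1 + (w - cfg.patch_size) // cfg.stride
    )
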