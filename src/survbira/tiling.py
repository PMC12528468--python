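"""Tissue detection, tiling into fixed-size patches, normalization, augmentation.

A pathology image is reduced to the set of S x S x 3 tiles that actually
contain tissue.  Background (near-white glass) is removed with a
saturation threshold: H&E-stained tissue is strongly colored (pink stroma,
purple nuclei) while empty glass is nearly achromatic, so Otsu's threshold
on the HSV saturation channel separates the two; a fixed fallback
threshold covers degenerate images where Otsu has nothing to split.
Each kept tile inherits the survival label of the slide's patient
(weak supervision: no region-level annotation exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import closing, footprint_rectangle

#: Saturation below which a pixel is considered achromatic background when
#: Otsu cannot find a meaningful split.
FALLBACK_SATURATION = 0.07


@dataclass
class TilingConfig:
    """Geometry and quality-control settings for tiling.

    patch_size : pixels per side of a tile (scientific default 512; tests
        use 64 to keep synthetic cohorts small).
    target_magnification : nominal objective power the image is assumed to
        be at (flat PNG/TIFF inputs are taken as already at this power).
    tissue_fraction_min : minimum fraction of tissue pixels for a tile to
        be kept.
    stride : pixels between tile origins; defaults to ``patch_size``
        (non-overlapping grid).
    """

    patch_size: int = 512
    target_magnification: float = 20.0
    tissue_fraction_min: float = 0.5
    stride: int | None = None

    def __post_init__(self) -> None:
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if not 0.0 <= self.tissue_fraction_min <= 1.0:
            raise ValueError("tissue_fraction_min must be in [0, 1]")
        if self.stride is None:
            self.stride = self.patch_size
        if self.stride <= 0:
            raise ValueError("stride must be positive")


@dataclass
class PatchRecord:
    """One tile: grid origin, pixel data, and the broadcast survival label.

    ``x`` and ``y`` are the 0-based top-left pixel coordinates of the
    half-open tile [x, x+S) x [y, y+S); ``x`` indexes columns and ``y``
    rows.  ``label_days`` equals the owning patient's survival time.
    """

    slide_id: str
    x: int
    y: int
    pixels: np.ndarray
    label_days: float = np.nan


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an RGB image with 3 channels, got shape {image.shape}; "
            "convert grayscale input to 3-channel RGB first"
        )
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    return np.clip(img, 0.0, 1.0)


def detect_tissue(image: np.ndarray, config: TilingConfig | None = None) -> np.ndarray:
    """Binary tissue mask for an RGB image.

    Saturation is thresholded by Otsu's method, falling back to a fixed
    cut (saturation > 0.07) when the image is effectively unimodal (e.g.
    uniform backgrounds, where Otsu's split is meaningless).  Near-white
    pixels are always background.  Small holes are closed morphologically.
    """
    img = _as_float_rgb(image)
    sat = rgb2hsv(img)[..., 1]
    near_white = img.min(axis=2) >= 0.95

    finite_sat = sat[~near_white]
    if finite_sat.size == 0 or np.ptp(sat) < 1e-3:
        thresh = FALLBACK_SATURATION
    else:
        try:
            thresh = threshold_otsu(sat)
        except ValueError:
            thresh = FALLBACK_SATURATION
        # Otsu on an almost-uniform saturation image returns an arbitrary
        # mid-value; guard with the fixed floor.
        thresh = max(thresh, FALLBACK_SATURATION)

    mask = (sat > thresh) & ~near_white
    mask = closing(mask, footprint_rectangle((5, 5)))
    mask &= ~near_white
    return mask


def tile_slide(
    image: np.ndarray,
    config: TilingConfig,
    mask: np.ndarray | None = None,
    label_days: float = np.nan,
    slide_id: str = "",
) -> list[PatchRecord]:
    """Cut the tissue regions of an image into fixed-size tiles.

    Tiles are laid on a regular grid with the configured stride starting
    at (0, 0); partial tiles at the right/bottom edges are discarded.  A
    tile is kept iff the fraction of mask-positive pixels inside it is at
    least ``tissue_fraction_min``.  Pixel data is returned unnormalized
    (as sliced from ``image``).
    """
    if mask is None:
        mask = detect_tissue(image, config)
    if mask.shape[:2] != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape[:2]} does not match image {image.shape[:2]}"
        )
    S, stride = config.patch_size, config.stride
    H, W = image.shape[:2]
    if H < S or W < S:
        warnings.warn(
            f"image {slide_id or '<unnamed>'} ({H}x{W}) smaller than patch size {S}; "
            "no tiles produced",
            stacklevel=2,
        )
        return []
    patches: list[PatchRecord] = []
    for y in range(0, H - S + 1, stride):
        for x in range(0, W - S + 1, stride):
            coverage = mask[y : y + S, x : x + S].mean()
            if coverage >= config.tissue_fraction_min:
                patches.append(
                    PatchRecord(
                        slide_id=slide_id,
                        x=x,
                        y=y,
                        pixels=image[y : y + S, x : x + S].copy(),
                        label_days=label_days,
                    )
                )
    return patches


def normalize_patch(pixels: np.ndarray) -> np.ndarray:
    """Map integer intensities in [0, 255] to floats in [0, 1] (v -> v/255)."""
    arr = np.asarray(pixels)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(
            f"pixel values outside [0, 255]: range [{arr.min()}, {arr.max()}]"
        )
    return arr.astype(np.float64) / 255.0


def augment_patch(
    pixels: np.ndarray,
    rng: np.random.Generator,
    contrast_range: tuple[float, float] = (0.8, 1.2),
    gamma_range: tuple[float, float] = (0.8, 1.2),
    brightness_range: tuple[float, float] = (-0.1, 0.1),
    p_apply: float = 0.5,
) -> np.ndarray:
    """Random contrast, gamma, and brightness on a [0, 1] patch.

    Each transform is applied independently with probability ``p_apply``:
    contrast rescales about the per-channel mean by c ~ U[0.8, 1.2], gamma
    maps v -> v**g with g ~ U[0.8, 1.2], brightness adds b ~ U[-0.1, 0.1].
    The result is clipped back to [0, 1].  Deterministic given ``rng``.
    """
    out = np.asarray(pixels, dtype=np.float64)
    if out.min() < 0 or out.max() > 1:
        raise ValueError("augment_patch expects a normalized [0, 1] patch")
    # Draw all randomness unconditionally so the rng stream does not depend
    # on which branches fire.
    apply = rng.random(3) < p_apply
    c = rng.uniform(*contrast_range)
    g = rng.uniform(*gamma_range)
    b = rng.uniform(*brightness_range)
    if apply[0]:
        mean = out.mean(axis=(0, 1), keepdims=True)
        out = mean + c * (out - mean)
    if apply[1]:
        out = np.clip(out, 0.0, 1.0) ** g
    if apply[2]:
        out = out + b
    return np.clip(out, 0.0, 1.0)
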