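"""Image preprocessing: plant-green color-range masking, resizing, splits.

Plant-seedling photographs are masked before training: pixels whose color
falls inside an inclusive per-channel window — bounds (27, 45, 45) to
(100, 255, 255) — keep their value, every other pixel is zeroed, leaving
the plant on a black background.  The window is applied, by default, to
the raw RGB channels exactly as the bounds are written; an HSV mode is
also provided because the same numbers read naturally as a green hue
window in HSV with hue on a 0-179 scale (the intent of the source bounds
is ambiguous, so both interpretations are first-class).  Images are then
resized to 224 x 224 (bilinear, aspect not preserved) and split into
stratified train/validation/test index sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import train_test_split

__all__ = [
    "MaskRange",
    "PLANT_GREEN_RANGE",
    "SplitSpec",
    "color_range_mask",
    "hsv_channels",
    "resize_image",
    "split_dataset",
]


@dataclass(frozen=True)
class MaskRange:
    """Inclusive per-channel color window.

    ``colorspace`` is ``"rgb"`` (bounds compared to the raw channels) or
    ``"hsv"`` (bounds compared to hue scaled to 0-179 and saturation/value
    scaled to 0-255).
    """

    lower: tuple[int, int, int] = (27, 45, 45)
    upper: tuple[int, int, int] = (100, 255, 255)
    colorspace: str = "rgb"

    def __post_init__(self):
        if self.colorspace not in ("rgb", "hsv"):
            raise ValueError(f"colorspace must be 'rgb' or 'hsv', got {self.colorspace!r}")
        for lo, hi in zip(self.lower, self.upper):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"invalid channel bounds [{lo}, {hi}]")


PLANT_GREEN_RANGE = MaskRange()


def hsv_channels(image: np.ndarray) -> np.ndarray:
    """HSV channels of an RGB image, scaled to (0-179, 0-255, 0-255)."""
    hsv = rgb2hsv(np.asarray(image, dtype=float) / 255.0)
    return hsv * np.array([179.0, 255.0, 255.0])


def color_range_mask(
    image: np.ndarray,
    mask_range: MaskRange = PLANT_GREEN_RANGE,
    return_mask: bool = False,
):
    """Zero every pixel outside the color window; keep the rest unchanged.

    Idempotent in RGB mode by construction (kept pixels are unchanged,
    zeroed pixels stay outside a window whose lower bounds are positive).
    Returns the masked raster, plus the boolean keep-mask when requested.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 raster, got shape {image.shape}")
    channels = (
        image.astype(float) if mask_range.colorspace == "rgb" else hsv_channels(image)
    )
    lower = np.asarray(mask_range.lower, dtype=float)
    upper = np.asarray(mask_range.upper, dtype=float)
    keep = np.all((channels >= lower) & (channels <= upper), axis=2)
    masked = np.where(keep[..., None], image, 0).astype(image.dtype)
    return (masked, keep) if return_mask else masked


def resize_image(image: np.ndarray, target: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Bilinear resize to ``target`` (height, width); aspect not preserved.

    Integer inputs come back as integers (rounded); floats stay float.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    if image.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-D raster, got shape {image.shape}")
    out_shape = tuple(target) + image.shape[2:]
    if image.shape[:2] == tuple(target):
        return image.copy()
    out = _sk_resize(
        image.astype(float), out_shape, order=1, preserve_range=True, anti_aliasing=False
    )
    if np.issubdtype(image.dtype, np.integer):
        return np.rint(out).astype(image.dtype)
    return out.astype(image.dtype)


@dataclass(frozen=True)
class SplitSpec:
    """Train/(validation)/test fractions with a seed and stratification flag.

    Two fractions give a train/test split, three give
    train/validation/test.  Fractions must be positive and sum to 1.
    """

    fractions: tuple[float, ...] = (0.7, 0.15, 0.15)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if len(self.fractions) not in (2, 3):
            raise ValueError("need 2 or 3 split fractions")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")


def split_dataset(labels: Sequence, spec: SplitSpec) -> tuple[np.ndarray, ...]:
    """Partition ``range(len(labels))`` into disjoint, exhaustive index sets.

    Stratified mode preserves per-class proportions to within one item per
    split; the same seed always yields the same partition.
    """
    labels = np.asarray(labels)
    n = len(labels)
    indices = np.arange(n)
    strat = labels if spec.stratified else None
    if len(spec.fractions) == 2:
        train_idx, test_idx = train_test_split(
            indices,
            test_size=spec.fractions[1],
            random_state=spec.seed,
            stratify=strat,
        )
        return np.sort(train_idx), np.sort(test_idx)
    f_train, f_val, f_test = spec.fractions
    train_idx, rest_idx = train_test_split(
        indices, test_size=f_val + f_test, random_state=spec.seed, stratify=strat
    )
    rest_strat = labels[rest_idx] if spec.stratified else None
    val_idx, test_idx = train_test_split(
        rest_idx,
        test_size=f_test / (f_val + f_test),
        random_state=spec.seed,
        stratify=rest_strat,
    )
    return np.sort(train_idx), np.sort(val_idx), np.sort(test_idx)
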