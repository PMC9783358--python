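"""Bounded position augmentation: exactly 8 variants per activity image.

Four techniques — reflection, rotation, scale, translation — each
applied at its lower and upper limit, give 8 deterministic variants per
original image and grow any dataset to 9x its size with class balance
untouched.  Reflection's two variants are the horizontal and vertical
mirror; rotation/scale act about the image center; pixels exposed by a
transform are filled with a constant intensity (black by default,
matching sensor silence after normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging import ActivityImage, round_half_up

__all__ = ["AugmentationConfig", "augment_image", "augment_dataset"]


@dataclass(frozen=True)
class AugmentationConfig:
    """Techniques and limits of the 8-variant augmentation.

    Defaults follow the bounded-position recipe: rotation +/-30 deg,
    translation +/-10 px (both axes jointly), scale 0.9-1.1, and the two
    reflection axes.  ``axis_separate_translation`` switches translation
    to four single-axis variants (right/left/up/down), yielding 10
    variants per image instead of 8 — it is therefore not the default.
    ``seed`` is reserved for a future random-within-limits mode; the
    default limit-value augmentation is fully deterministic.
    """

    rotation_limits: tuple[float, float] = (-30.0, 30.0)
    translation_limits: tuple[int, int] = (-10, 10)
    scale_limits: tuple[float, float] = (0.9, 1.1)
    reflection_axes: tuple[str, str] = ("horizontal", "vertical")
    fill_value: int = 0
    axis_separate_translation: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("rotation_limits", "translation_limits", "scale_limits"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower limit {lo} must be < upper limit {hi}")
        if not 0 <= self.fill_value <= 255:
            raise ValueError(f"fill_value must be in [0, 255], got {self.fill_value}")
        for axis in self.reflection_axes:
            if axis not in ("horizontal", "vertical"):
                raise ValueError(f"unknown reflection axis {axis!r}")

    @property
    def n_variants(self) -> int:
        return 10 if self.axis_separate_translation else 8


def _finalize(pixels: np.ndarray) -> np.ndarray:
    return np.clip(round_half_up(pixels), 0, 255).astype(np.uint8)


def _reflect(pixels: np.ndarray, axis: str) -> np.ndarray:
    # horizontal reflection mirrors left-right, vertical mirrors up-down
    return np.fliplr(pixels) if axis == "horizontal" else np.flipud(pixels)


def _rotate(pixels: np.ndarray, degrees: float, fill: float) -> np.ndarray:
    out = ndimage.rotate(
        pixels.astype(float),
        angle=degrees,
        reshape=False,
        order=1,
        mode="constant",
        cval=fill,
    )
    return _finalize(out)


def _scale(pixels: np.ndarray, factor: float, fill: float) -> np.ndarray:
    # zoom about the image center, keeping the canvas size fixed:
    # input_coord = center + (output_coord - center) / factor
    center = (np.array(pixels.shape, dtype=float) - 1.0) / 2.0
    matrix = np.eye(2) / factor
    offset = center - matrix @ center
    out = ndimage.affine_transform(
        pixels.astype(float),
        matrix,
        offset=offset,
        order=1,
        mode="constant",
        cval=fill,
    )
    return _finalize(out)


def _translate(pixels: np.ndarray, dx: int, dy: int, fill: float) -> np.ndarray:
    out = ndimage.shift(
        pixels.astype(float),
        shift=(dy, dx),
        order=1,
        mode="constant",
        cval=fill,
    )
    return _finalize(out)


def augment_image(img: ActivityImage, cfg: AugmentationConfig | None = None) -> list[ActivityImage]:
    """Produce the deterministic augmented variants of one square image.

    Default order: reflect-horizontal, reflect-vertical, rotate at the
    lower and upper angle, scale at the lower and upper factor,
    translate at the lower and upper offset (applied to both axes
    jointly).  Every output keeps the input's dimensions, label and
    source id; provenance records ``technique_limit``.
    """
    cfg = cfg or AugmentationConfig()
    if not img.is_square:
        raise ValueError(f"augmentation expects a square image, got {img.pixels.shape}")
    fill = float(cfg.fill_value)
    px = img.pixels
    variants: list[ActivityImage] = []
    for axis in cfg.reflection_axes:
        variants.append(img.with_pixels(_reflect(px, axis), f"reflect_{axis}"))
    for angle in cfg.rotation_limits:
        variants.append(img.with_pixels(_rotate(px, angle, fill), f"rotate_{angle:+g}"))
    for factor in cfg.scale_limits:
        variants.append(img.with_pixels(_scale(px, factor, fill), f"scale_{factor:g}"))
    if cfg.axis_separate_translation:
        lo, hi = cfg.translation_limits
        moves = [(lo, 0), (hi, 0), (0, lo), (0, hi)]
    else:
        moves = [(t, t) for t in cfg.translation_limits]
    for dx, dy in moves:
        variants.append(
            img.with_pixels(_translate(px, dx, dy, fill), f"translate_{dx:+d}_{dy:+d}")
        )
    return variants


def augment_dataset(
    images: Sequence[ActivityImage], cfg: AugmentationConfig | None = None
) -> list[ActivityImage]:
    """Originals plus all augmented variants.

    With the default config the output has exactly ``9 * len(images)``
    entries and every per-class count is multiplied by 9, so class
    proportions are unchanged.
    """
    if len(images) == 0:
        raise ValueError("augment_dataset needs a non-empty image list")
    cfg = cfg or AugmentationConfig()
    out: list[ActivityImage] = []
    for img in images:
        out.append(img)
        out.extend(augment_image(img, cfg))
    return out
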