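"""Turn normalized sensor windows into grayscale activity images.

Each sensor sample becomes one pixel: a channels x window_len window is
multiplied by 255 (round half up) so brightness tracks the sensor value,
each channel row is replicated an equal integer number of times to make
the matrix approximately square, and the result is interpolated to the
classifier input size (224 x 224 by default).  Images round-trip as
8-bit grayscale PNGs with a JSON sidecar manifest carrying label and
provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .preprocess import Window

__all__ = [
    "ActivityImage",
    "DatasetIntegrityError",
    "load_dataset",
    "load_image",
    "resize_to_square",
    "save_dataset",
    "save_image",
    "window_to_activity_image",
    "window_to_image",
    "windows_to_images",
]

MANIFEST_NAME = "manifest.json"


class DatasetIntegrityError(RuntimeError):
    """An image directory and its manifest disagree."""


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class ActivityImage:
    """A square grayscale image derived from one sensor window.

    ``provenance`` is ``"original"`` for a direct conversion or the
    ``technique_limit`` tag of the augmentation that produced it.
    """

    pixels: np.ndarray  # uint8, H x W
    label: str
    provenance: str = "original"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D intensity matrix")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def is_square(self) -> bool:
        return self.pixels.shape[0] == self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray, provenance: str) -> "ActivityImage":
        return replace(self, pixels=pixels, provenance=provenance)


def window_to_image(w: Window) -> np.ndarray:
    """Map a normalized window to a raw channels x window_len intensity
    matrix: ``pixel[i, j] = round(255 * values[i, j])`` (round half up).

    Raises a contract error naming the offending channel if any value
    falls outside [0, 1].
    """
    vals = w.values
    for i in range(w.n_channels):
        row = vals[i]
        if row.min() < 0.0 or row.max() > 1.0:
            raise ValueError(
                f"window values outside [0, 1] in channel index {i} "
                f"(min {row.min():g}, max {row.max():g}); normalize first"
            )
    return round_half_up(255.0 * vals).astype(np.uint8)


def resize_to_square(
    img: np.ndarray, side: int = 224, interpolation: str = "bilinear"
) -> np.ndarray:
    """Resize a raw intensity matrix to ``side x side``.

    Two stages: (1) every channel row is replicated ``k = round(W / H)``
    times (at least once) so each channel becomes a contiguous
    horizontal band and the matrix is approximately square; (2) the
    banded matrix is interpolated to the target size.  Constant inputs
    stay exactly constant and outputs are clamped to [0, 255].
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    h, w = img.shape
    k = max(1, round(w / h))
    banded = np.repeat(img, k, axis=0)
    if banded.shape == (side, side):
        out = banded
    else:
        out = _sk_resize(
            banded,
            (side, side),
            order=order,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    return np.clip(round_half_up(out), 0, 255).astype(np.uint8)


def window_to_activity_image(
    w: Window, side: int = 224, interpolation: str = "bilinear"
) -> ActivityImage:
    """Full conversion of one window: intensity mapping then resize."""
    return ActivityImage(
        pixels=resize_to_square(window_to_image(w), side, interpolation),
        label=w.label,
        provenance="original",
        source_id=f"{w.source_id}:{w.start_index}",
    )


def windows_to_images(
    windows: Sequence[Window], side: int = 224, interpolation: str = "bilinear"
) -> list[ActivityImage]:
    """Convert a whole cohort; one image per window, class counts preserved."""
    return [window_to_activity_image(w, side, interpolation) for w in windows]


# -- PNG + manifest persistence ------------------------------------------------


def save_image(img: ActivityImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG (lossless)."""
    Image.fromarray(img.pixels, mode="L").save(Path(path), format="PNG")


def load_image(
    path: str | Path, label: str = "", provenance: str = "original", source_id: str = ""
) -> ActivityImage:
    """Read an 8-bit grayscale PNG back into an :class:`ActivityImage`."""
    with Image.open(Path(path)) as im:
        pixels = np.asarray(im.convert("L"), dtype=np.uint8)
    return ActivityImage(pixels=pixels, label=label, provenance=provenance, source_id=source_id)


def save_dataset(images: Iterable[ActivityImage], directory: str | Path) -> Path:
    """Write a batch of images as PNGs plus a JSON manifest.

    Returns the manifest path.  File names are ``img_<index>.png`` in
    input order so re-runs with identical inputs are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, img in enumerate(images):
        name = f"img_{i:06d}.png"
        save_image(img, directory / name)
        records.append(
            {
                "file": name,
                "label": img.label,
                "provenance": img.provenance,
                "source_id": img.source_id,
            }
        )
    manifest = directory / MANIFEST_NAME
    manifest.write_text(json.dumps({"images": records}, indent=1, sort_keys=True))
    return manifest


def load_dataset(directory: str | Path) -> list[ActivityImage]:
    """Load every image listed in a directory's manifest.

    Raises :class:`DatasetIntegrityError` when a listed file is absent
    or a PNG in the directory has no manifest entry.
    """
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise DatasetIntegrityError(f"no {MANIFEST_NAME} in {directory}")
    records = json.loads(manifest.read_text())["images"]
    listed = {r["file"] for r in records}
    on_disk = {p.name for p in directory.glob("*.png")}
    unlisted = on_disk - listed
    if unlisted:
        raise DatasetIntegrityError(
            f"{len(unlisted)} PNG(s) missing from manifest, e.g. {sorted(unlisted)[0]}"
        )
    missing = listed - on_disk
    if missing:
        raise DatasetIntegrityError(
            f"{len(missing)} manifest entr(ies) without a file, e.g. {sorted(missing)[0]}"
        )
    return [
        load_image(
            directory / r["file"],
            label=r["label"],
            provenance=r.get("provenance", "original"),
            source_id=r.get("source_id", ""),
        )
        for r in records
    ]
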