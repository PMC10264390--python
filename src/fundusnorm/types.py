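"""Core containers and image I/O helpers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph plus identity metadata.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
    image_id, participant_id, eye, dataset : identity metadata; ``eye`` is
        one of ``L``, ``R`` or ``unknown``.
    fov_degrees : nominal camera field of view in degrees (30 = disc-centered
        standard; 45 = typical macula-centered capture).
    """

    pixels: np.ndarray
    image_id: str = ""
    participant_id: str = ""
    eye: str = "unknown"
    dataset: str = ""
    fov_degrees: float = 30.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must have shape (H, W, 3), got {px.shape}")
        if px.dtype != np.uint8:
            px = np.clip(np.round(px), 0, 255).astype(np.uint8)
        if self.eye not in ("L", "R", "unknown"):
            raise ValueError(f"eye must be L, R or unknown, got {self.eye!r}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "FundusImage":
        """Copy of this image with new pixel data, metadata preserved."""
        return replace(self, pixels=pixels)


def write_image(path: str | Path, image: FundusImage | np.ndarray) -> None:
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    iio.imwrite(Path(path), px)


def read_image(path: str | Path, **meta) -> FundusImage:
    px = iio.imread(Path(path))
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[2] == 4:
        px = px[:, :, :3]
    return FundusImage(pixels=px.astype(np.uint8), **meta)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127
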