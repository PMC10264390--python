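"""Illumination correction and final model-input preparation.

Retinal curvature makes fundus photographs unevenly lit. The correction
estimates a per-channel background by large-kernel Gaussian smoothing and
divides the image by it (or subtracts it), rescaling so the global channel
means are preserved. The background is estimated by normalized convolution
restricted to the camera aperture, so the black exterior does not bias it
near the rim. The default kernel scale (sigma = 0.05 of the image height,
i.e. ~h/20, in line with standard fundus shade-correction kernels) is wide
compared to vessels yet narrow enough to track lighting fields that span
the whole aperture.

Model-ready inputs are 512 x 512 x 3 arrays scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _resize

from fundusnorm.types import FundusImage


@dataclass
class CorrectionParams:
    """Background-estimation parameters.

    sigma_frac: Gaussian sigma as a fraction of image height. mode: "divide"
    cancels multiplicative shading (the physical model for curvature
    vignetting); "subtract" removes an additive offset instead.
    """

    sigma_frac: float = 0.05
    mode: str = "divide"

    def validate(self) -> None:
        if self.sigma_frac <= 0:
            raise ValueError(f"sigma_frac must be > 0, got {self.sigma_frac}")
        if self.mode not in ("divide", "subtract"):
            raise ValueError(f"mode must be divide or subtract, got {self.mode!r}")


def correct_illumination(
    image: FundusImage, params: CorrectionParams | None = None
) -> FundusImage:
    """Flatten smooth lighting gradients while preserving channel means.

    Black aperture-exterior pixels stay black under division (0 / background
    = 0) and outputs are clipped to the 8-bit range, so no halo can exceed
    the valid range.
    """
    params = params or CorrectionParams()
    params.validate()
    px = image.pixels.astype(np.float64)
    h, w = px.shape[:2]
    sigma = params.sigma_frac * h
    if sigma >= min(h, w):
        raise ValueError(
            f"smoothing kernel (sigma {sigma:.0f} px) exceeds image size {h}x{w}"
        )
    # normalized convolution restricted to the camera aperture: the black
    # exterior must not drag the background estimate down near the rim
    fov = px.mean(axis=2) > 5.0
    if not fov.any():
        return image.with_pixels(image.pixels.copy())
    weight = fov.astype(np.float64)
    denom = np.maximum(ndimage.gaussian_filter(weight, sigma), 1e-6)
    out = np.empty_like(px)
    for ch in range(3):
        img_c = px[:, :, ch]
        bg_c = ndimage.gaussian_filter(img_c * weight, sigma) / denom
        bg_c = np.maximum(bg_c, 1e-6)
        if params.mode == "divide":
            flat = img_c / bg_c
            flat_mean = flat[fov].mean()
            scale = img_c[fov].mean() / flat_mean if flat_mean > 0 else 0.0
            out[:, :, ch] = flat * scale
        else:
            flat = img_c - bg_c
            out[:, :, ch] = flat + img_c[fov].mean() - flat[fov].mean()
            out[:, :, ch][~fov] = img_c[~fov]
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return image.with_pixels(out)


def finalize_input(image: FundusImage | np.ndarray, size: int = 512) -> np.ndarray:
    """Resize to size x size x 3 and scale 8-bit values into [0, 1]."""
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {px.shape}")
    arr = px.astype(np.float64)
    if arr.shape[0] != size or arr.shape[1] != size:
        arr = _resize(arr, (size, size, 3), order=1, anti_aliasing=True, preserve_range=True)
    return np.clip(arr / 255.0, 0.0, 1.0)
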