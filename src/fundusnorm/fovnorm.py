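"""Field-of-view normalization to 30-degree disc-centered images.

The development standard is a 30-degree disc-centered photograph in which
the vertical optic-disc extent is 0.23 of the image height. Any image with
a wider field of view is reduced to that standard by cropping a square
window around the detected disc:

    crop factor = disc_ratio_original / 0.23

with the window side equal to the crop factor times the source image
height. A 45-degree capture (disc ratio ~0.15) therefore gets a crop factor
of ~0.65. Windows that overrun the frame are zero-padded. Images whose disc
ratio exceeds 0.23 (sub-30-degree or pre-cropped inputs) are instead
extended by border replication until the disc ratio reaches 0.23; the
replicated (synthetic) frame is blacked out after illumination correction.

Disc ratios are averaged per image size, falling back to the global mean
for sizes with fewer than ten cases, so that a uniform crop factor per
size group preserves the natural heterogeneity in optic disc size.
Alternative modes (fixed factor, random factor, per-image disc rescaling,
passthrough resize) support sensitivity analyses of the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from skimage.transform import resize as _resize

from fundusnorm.qc import DiscDetection
from fundusnorm.types import FundusImage

#: mean disc ratio of 30-degree disc-centered reference images
REFERENCE_DISC_RATIO = 0.23

#: bounds of the uniform distribution used by the random-crop-factor mode
RANDOM_FACTOR_RANGE = (0.40, 0.80)

MODES = ("standard_grouped", "fixed_factor", "random_factor", "rescale_disc", "extend", "passthrough")


def crop_factor(disc_ratio_original: float, reference: float = REFERENCE_DISC_RATIO) -> float:
    """Scale factor mapping a source image height to a 30-degree window."""
    if not 0.0 < disc_ratio_original <= 1.0:
        raise ValueError(f"disc_ratio_original must lie in (0, 1], got {disc_ratio_original}")
    if not 0.0 < reference <= 1.0:
        raise ValueError(f"reference must lie in (0, 1], got {reference}")
    return disc_ratio_original / reference


@dataclass
class DiscRatioTable:
    """Mean disc ratio per image size with a small-group fallback.

    Sizes observed fewer than ``min_count`` times resolve to the global
    mean over all detections.
    """

    per_size: dict[tuple[int, int], float]
    counts: dict[tuple[int, int], int]
    global_mean: float
    min_count: int = 10

    def lookup(self, shape: tuple[int, int]) -> float:
        shape = (int(shape[0]), int(shape[1]))
        if self.counts.get(shape, 0) >= self.min_count:
            return self.per_size[shape]
        return self.global_mean


def build_disc_ratio_table(
    entries: list[tuple[tuple[int, int], float]], min_count: int = 10
) -> DiscRatioTable:
    """Average disc ratios per image size.

    ``entries`` pairs each detection's source image shape (H, W) with its
    measured disc ratio.
    """
    if not entries:
        raise ValueError("at least one detection is required")
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    all_ratios = []
    for shape, ratio in entries:
        key = (int(shape[0]), int(shape[1]))
        sums[key] = sums.get(key, 0.0) + ratio
        counts[key] = counts.get(key, 0) + 1
        all_ratios.append(ratio)
    per_size = {k: sums[k] / counts[k] for k in sums}
    return DiscRatioTable(
        per_size=per_size,
        counts=counts,
        global_mean=float(np.mean(all_ratios)),
        min_count=min_count,
    )


@dataclass
class TransformPlan:
    """Geometry bookkeeping mapping a source image to the output frame."""

    mode: str
    crop_factor: float | None = None
    reference_disc_ratio: float = REFERENCE_DISC_RATIO
    crop_window: tuple[int, int, int] | None = None  # (row0, col0, side), source frame
    pad_record: dict[str, int] = field(default_factory=dict)
    extension_record: dict[str, int] | None = None
    output_size: int = 512
    source_shape: tuple[int, int] | None = None

    def to_json(self) -> str:
        d = {
            "mode": self.mode,
            "crop_factor": self.crop_factor,
            "reference_disc_ratio": self.reference_disc_ratio,
            "crop_window": list(self.crop_window) if self.crop_window else None,
            "pad_record": self.pad_record,
            "extension_record": self.extension_record,
            "output_size": self.output_size,
            "source_shape": list(self.source_shape) if self.source_shape else None,
        }
        return json.dumps(d)


def plan_crop(
    detection: DiscDetection,
    image_shape: tuple[int, int],
    mode: str = "standard_grouped",
    *,
    table: DiscRatioTable | None = None,
    fixed_factor: float | None = None,
    rng: np.random.Generator | None = None,
    reference: float = REFERENCE_DISC_RATIO,
    output_size: int = 512,
) -> TransformPlan:
    """Resolve the crop factor for one image according to the chosen mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "standard_grouped":
        if table is None:
            raise ValueError("standard_grouped mode requires a DiscRatioTable")
        cf = crop_factor(table.lookup(image_shape), reference)
    elif mode == "fixed_factor":
        if fixed_factor is None:
            raise ValueError("fixed_factor mode requires fixed_factor")
        cf = float(fixed_factor)
    elif mode == "random_factor":
        if rng is None:
            raise ValueError("random_factor mode requires an rng")
        cf = random_crop_factor(rng)
    elif mode == "rescale_disc":
        cf = crop_factor(detection.disc_ratio, reference)
    elif mode == "passthrough":
        cf = None
    else:  # extend is planned by extend_to_30
        raise ValueError("extend mode is planned by extend_to_30")
    return TransformPlan(
        mode=mode,
        crop_factor=cf,
        reference_disc_ratio=reference,
        output_size=output_size,
        source_shape=(int(image_shape[0]), int(image_shape[1])),
    )


def random_crop_factor(rng: np.random.Generator) -> float:
    """Uniform draw from the sensitivity-analysis range [0.40, 0.80]."""
    lo, hi = RANDOM_FACTOR_RANGE
    return float(rng.uniform(lo, hi))


def _resize_array(arr: np.ndarray, size: int, is_mask: bool) -> np.ndarray:
    if arr.shape[0] == size and arr.shape[1] == size:
        return arr.copy()
    if is_mask:
        out = _resize(
            arr.astype(np.float32), (size, size), order=0, anti_aliasing=False,
            preserve_range=True,
        )
        return out > 0.5
    out = _resize(
        arr.astype(np.float64), (size, size) + arr.shape[2:], order=1,
        anti_aliasing=True, preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _extract_window(
    arr: np.ndarray, window: tuple[int, int, int]
) -> tuple[np.ndarray, dict[str, int]]:
    """Copy a square window out of ``arr``, zero-filling out-of-bounds area."""
    r0, c0, side = window
    h, w = arr.shape[:2]
    out_shape = (side, side) + arr.shape[2:]
    out = np.zeros(out_shape, dtype=arr.dtype)
    r1, c1 = r0 + side, c0 + side
    sr0, sr1 = max(r0, 0), min(r1, h)
    sc0, sc1 = max(c0, 0), min(c1, w)
    pad = {
        "top": min(max(-r0, 0), side),
        "bottom": min(max(r1 - h, 0), side),
        "left": min(max(-c0, 0), side),
        "right": min(max(c1 - w, 0), side),
    }
    if sr0 < sr1 and sc0 < sc1:
        out[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = arr[sr0:sr1, sc0:sc1]
    return out, pad


def crop_disc_centered(
    image: FundusImage, detection: DiscDetection, plan: TransformPlan
) -> tuple[FundusImage, TransformPlan]:
    """Crop a square disc-centered window and resize to the output size.

    The window side is round(crop_factor * source height), centered on the
    detected disc centroid; area falling outside the source frame is
    zero-padded. Passthrough mode skips the crop and only resizes.
    """
    px = image.pixels
    h = px.shape[0]
    if plan.mode == "passthrough":
        out = _resize_array(px, plan.output_size, is_mask=False)
        plan.crop_window = None
        plan.pad_record = {"top": 0, "bottom": 0, "left": 0, "right": 0}
        return image.with_pixels(out), plan
    if plan.crop_factor is None:
        raise ValueError("plan.crop_factor must be resolved before cropping")
    side = int(round(plan.crop_factor * h))
    if side < 8:
        raise ValueError(f"degenerate crop: window side {side} px < 8 px")
    cy, cx = detection.centroid
    r0 = int(round(cy - side / 2.0))
    c0 = int(round(cx - side / 2.0))
    window = (r0, c0, side)
    cropped, pad = _extract_window(px, window)
    plan.crop_window = window
    plan.pad_record = pad
    plan.source_shape = (px.shape[0], px.shape[1])
    out = _resize_array(cropped, plan.output_size, is_mask=False)
    result = image.with_pixels(out)
    result.fov_degrees = image.fov_degrees * plan.crop_factor
    return result, plan


def apply_plan_to_mask(mask: np.ndarray, plan: TransformPlan) -> np.ndarray:
    """Transform a binary mask through the same geometry as its image."""
    mask = np.asarray(mask, dtype=bool)
    if plan.mode == "extend":
        if plan.extension_record is None:
            raise ValueError("extend plan lacks an extension_record")
        e = plan.extension_record
        return np.pad(
            mask, ((e["top"], e["bottom"]), (e["left"], e["right"])), mode="constant"
        )
    if plan.mode == "passthrough" or plan.crop_window is None:
        return _resize_array(mask, plan.output_size, is_mask=True)
    windowed, _ = _extract_window(mask, plan.crop_window)
    return _resize_array(windowed, plan.output_size, is_mask=True)


def extend_to_30(
    image: FundusImage,
    detection: DiscDetection,
    target: float = REFERENCE_DISC_RATIO,
) -> tuple[FundusImage, TransformPlan]:
    """Extend a sub-30-degree image by border replication.

    The frame is grown by copying the border values outward, symmetrically
    per axis (odd remainders go to the bottom/right edge), until the disc
    ratio equals ``target`` within one pixel. Width grows in proportion so
    the aspect ratio is preserved. The per-edge replication widths are
    recorded so the synthetic frame can be blacked out later.
    """
    px = image.pixels
    h, w = px.shape[:2]
    extent = detection.vertical_extent
    if extent / h <= target:
        raise ValueError(
            f"extension not needed: disc ratio {extent / h:.3f} <= target {target}"
        )
    new_h = int(round(extent / target))
    new_w = int(round(w * new_h / h))
    dh, dw = new_h - h, new_w - w
    record = {
        "top": dh // 2,
        "bottom": dh - dh // 2,
        "left": dw // 2,
        "right": dw - dw // 2,
    }
    extended = np.pad(
        px,
        ((record["top"], record["bottom"]), (record["left"], record["right"]), (0, 0)),
        mode="edge",
    )
    plan = TransformPlan(
        mode="extend",
        crop_factor=None,
        extension_record=record,
        output_size=512,
        source_shape=(h, w),
    )
    result = image.with_pixels(extended)
    return result, plan


def blackout_synthetic(image: FundusImage, plan: TransformPlan) -> FundusImage:
    """Replace border-replicated (synthetic) image area with black pixels.

    Applied after illumination correction so the synthetic frame can still
    support the background estimate, but never reaches the risk scorer.
    Idempotent.
    """
    if plan.extension_record is None:
        raise ValueError("plan has no extension_record")
    e = plan.extension_record
    px = image.pixels.copy()
    h, w = px.shape[:2]
    if e["top"]:
        px[: e["top"], :] = 0
    if e["bottom"]:
        px[h - e["bottom"] :, :] = 0
    if e["left"]:
        px[:, : e["left"]] = 0
    if e["right"]:
        px[:, w - e["right"] :] = 0
    return image.with_pixels(px)


def rescale_all_discs(
    image: FundusImage,
    detection: DiscDetection,
    target_ratio: float = REFERENCE_DISC_RATIO,
    output_size: int = 512,
) -> tuple[FundusImage, TransformPlan]:
    """Crop with a per-image factor so every output disc measures the same.

    Unlike the grouped standard mode this removes the natural heterogeneity
    in optic disc size: every output disc ratio becomes ``target_ratio``.
    """
    plan = TransformPlan(
        mode="rescale_disc",
        crop_factor=crop_factor(detection.disc_ratio, target_ratio),
        reference_disc_ratio=target_ratio,
        output_size=output_size,
    )
    return crop_disc_centered(image, detection, plan)
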