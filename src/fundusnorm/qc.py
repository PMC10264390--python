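"""Optic-disc quality control.

Candidate disc segmentations are screened against two realism criteria:

* the disc ratio (vertical disc extent / image height) must lie in
  [0.10, 0.40] for images with a field of view of at least 30 degrees;
* among surviving candidates, the one whose first Hu invariant moment is
  closest to the perfect-circle value 1/(2*pi) ~ 0.159 is selected,
  discarding oblong non-circular objects.

Images with no surviving candidate are discarded automatically. When a
ground-truth disc mask is supplied, segmentation and screening are skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from fundusnorm.types import FundusImage

#: first Hu invariant of a solid disk, the circularity target
HU_CIRCLE = 1.0 / (2.0 * np.pi)

#: admissible disc-ratio range for >= 30-degree fields of view
DISC_RATIO_BOUNDS = (0.10, 0.40)


def hu_moment_first(mask: np.ndarray) -> float:
    """First Hu invariant moment (eta20 + eta02) of a binary mask.

    Invariant to translation, scale and rotation; minimized (at 1/(2*pi))
    by a solid disk, so it grows as a shape becomes more elongated.
    """
    mask = np.asarray(mask, dtype=bool)
    m00 = mask.sum()
    if m00 == 0:
        raise ValueError("no foreground: mask is empty")
    rows, cols = np.nonzero(mask)
    rbar = rows.mean()
    cbar = cols.mean()
    mu20 = ((rows - rbar) ** 2).sum()
    mu02 = ((cols - cbar) ** 2).sum()
    norm = float(m00) ** 2
    return float((mu20 + mu02) / norm)


def _vertical_extent(mask: np.ndarray) -> int:
    rows = np.nonzero(np.any(mask, axis=1))[0]
    if rows.size == 0:
        return 0
    return int(rows[-1] - rows[0] + 1)


@dataclass
class DiscDetection:
    """One optic-nerve-head candidate with its screening measurements."""

    component_id: int
    centroid: tuple[float, float]
    vertical_extent: int
    disc_ratio: float
    hu_moment_1: float
    accepted: bool
    area: int = 0
    reject_reason: str | None = None


def detection_from_mask(
    mask: np.ndarray, image_height: int | None = None, component_id: int = 0
) -> DiscDetection:
    """Measure a single (trusted) disc mask without screening it."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no foreground: mask is empty")
    h = image_height if image_height is not None else mask.shape[0]
    rows, cols = np.nonzero(mask)
    extent = _vertical_extent(mask)
    return DiscDetection(
        component_id=component_id,
        centroid=(float(rows.mean()), float(cols.mean())),
        vertical_extent=extent,
        disc_ratio=extent / h,
        hu_moment_1=hu_moment_first(mask),
        accepted=True,
        area=int(mask.sum()),
    )


def screen_candidates(
    components: list[np.ndarray],
    image_height: int,
    ratio_bounds: tuple[float, float] = DISC_RATIO_BOUNDS,
) -> tuple[list[DiscDetection], int | None, str | None]:
    """Screen disc candidates and select the most circular admissible one.

    Candidates whose disc ratio falls outside ``ratio_bounds`` are rejected.
    Among survivors the candidate with |hu_moment_1 - 1/(2*pi)| minimal is
    selected; ties are broken by larger area, then lower component id.

    Returns (detections, selected component id or None, discard reason or
    None). A None selection means the image should be discarded.
    """
    if not components:
        return [], None, "no candidates"
    lo, hi = ratio_bounds
    detections = []
    for cid, comp in enumerate(components):
        det = detection_from_mask(comp, image_height=image_height, component_id=cid)
        if not lo <= det.disc_ratio <= hi:
            det.accepted = False
            det.reject_reason = "disc ratio out of bounds"
        detections.append(det)
    survivors = [d for d in detections if d.accepted]
    if not survivors:
        return detections, None, "disc ratio out of bounds"
    selected = min(
        survivors,
        key=lambda d: (abs(d.hu_moment_1 - HU_CIRCLE), -d.area, d.component_id),
    )
    for d in detections:
        if d is not selected and d.accepted:
            d.accepted = False
            d.reject_reason = "not most circular"
    return detections, selected.component_id, None


def segment_disc_simple(
    image: FundusImage | np.ndarray, min_area_frac: float = 2e-4
) -> list[np.ndarray]:
    """Threshold-based optic-disc candidate segmentation.

    The optic disc is the brightest extended structure in a fundus image, so
    Otsu thresholding of the mean-channel intensity inside the camera
    aperture, followed by morphological closing and hole filling (vessels
    crossing the disc punch dark gaps), yields candidate components. Returns
    each connected component of at least ``min_area_frac`` of the frame as
    its own mask; may return an empty list.
    """
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    gray = px.astype(np.float64).mean(axis=2)
    inside = gray > 10.0
    if inside.sum() < 16:
        return []
    thr = threshold_otsu(gray[inside])
    fg = (gray > thr) & inside
    if not fg.any():
        return []
    radius = max(2, px.shape[0] // 170)
    fg = morphology.closing(fg, morphology.disk(radius))
    fg = ndimage.binary_fill_holes(fg)
    labeled = measure.label(fg)
    min_area = max(16, int(min_area_frac * px.shape[0] * px.shape[1]))
    masks = []
    for lab in range(1, labeled.max() + 1):
        comp = labeled == lab
        if comp.sum() >= min_area:
            masks.append(comp)
    return masks


@dataclass
class ImageQC:
    """Outcome of quality control for one image."""

    image_id: str
    status: str  # "kept" or "discarded"
    reason: str | None
    detection: DiscDetection | None
    candidates: list[DiscDetection] = field(default_factory=list)


@dataclass
class QCReport:
    """Per-image QC outcomes plus the dataset-level removal rate (percent)."""

    results: list[ImageQC]

    @property
    def n_total(self) -> int:
        return len(self.results)

    @property
    def n_kept(self) -> int:
        return sum(1 for r in self.results if r.status == "kept")

    @property
    def removal_rate(self) -> float:
        if not self.results:
            return 0.0
        return removal_rate(self.n_total, self.n_kept)

    def kept(self) -> list[ImageQC]:
        return [r for r in self.results if r.status == "kept"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            det = r.detection
            rows.append(
                {
                    "image_id": r.image_id,
                    "status": r.status,
                    "reason": r.reason if r.reason else "",
                    "disc_ratio": det.disc_ratio if det else np.nan,
                    "hu_moment": det.hu_moment_1 if det else np.nan,
                }
            )
        return pd.DataFrame(
            rows, columns=["image_id", "status", "reason", "disc_ratio", "hu_moment"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "removal_rate_percent": self.removal_rate,
            "images": [
                {
                    "image_id": r.image_id,
                    "status": r.status,
                    "reason": r.reason,
                    "detection": asdict(r.detection) if r.detection else None,
                }
                for r in self.results
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def removal_rate(total: int, kept: int) -> float:
    """Percentage of images discarded: 100 * (total - kept) / total."""
    if total <= 0:
        raise ValueError("total must be positive")
    if kept > total or kept < 0:
        raise ValueError("kept must lie in [0, total]")
    return 100.0 * (total - kept) / total


def qc_image(
    image: FundusImage,
    mask: np.ndarray | None = None,
    ratio_bounds: tuple[float, float] = DISC_RATIO_BOUNDS,
) -> ImageQC:
    """Run quality control for one image.

    A supplied ground-truth mask bypasses segmentation and screening. For
    images declaring a field of view below 30 degrees the disc-ratio bounds
    do not apply (they are conditional on >= 30-degree capture), so the
    largest segmented component is taken as the disc without screening.
    """
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.pixels.shape[:2]:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape "
                f"{image.pixels.shape[:2]}"
            )
        det = detection_from_mask(mask, image_height=image.height)
        return ImageQC(image.image_id, "kept", None, det, [det])

    components = segment_disc_simple(image)
    if not components:
        return ImageQC(image.image_id, "discarded", "no candidates", None, [])

    if image.fov_degrees < 30.0:
        biggest = max(range(len(components)), key=lambda i: components[i].sum())
        det = detection_from_mask(
            components[biggest], image_height=image.height, component_id=biggest
        )
        return ImageQC(image.image_id, "kept", None, det, [det])

    detections, selected, reason = screen_candidates(
        components, image.height, ratio_bounds
    )
    if selected is None:
        return ImageQC(image.image_id, "discarded", reason, None, detections)
    det = detections[selected]
    return ImageQC(image.image_id, "kept", None, det, detections)


def qc_dataset(
    images: list[FundusImage],
    masks: list[np.ndarray | None] | dict[str, np.ndarray] | None = None,
) -> QCReport:
    """Quality-control a dataset; user-supplied masks bypass screening."""
    results = []
    for i, image in enumerate(images):
        if masks is None:
            mask = None
        elif isinstance(masks, dict):
            mask = masks.get(image.image_id)
        else:
            mask = masks[i]
        results.append(qc_image(image, mask=mask))
    return QCReport(results=results)
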