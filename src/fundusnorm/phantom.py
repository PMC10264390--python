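"""Synthetic fundus phantoms with ground-truth disc/cup masks.

A phantom is a minimal stand-in for a color fundus photograph: an orange
retinal background inside a circular camera aperture, a bright (slightly
vertically oval) optic disc with a nested brighter cup, dark vessel strokes
radiating from the disc, and a smooth multiplicative illumination gradient.
Every geometric property that the downstream quality-control and
field-of-view-normalization stages measure — disc ratio, vertical cup-disc
ratio (VCDR), disc center — is controlled exactly, so phantoms serve as
ground truth for the whole pipeline.

Cohorts emulate population screening data: two eyes per participant,
participant-level glaucoma labels at a controlled prevalence, and VCDR drawn
from separate Beta distributions for glaucomatous and healthy eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fundusnorm._rng import derive_rng
from fundusnorm.types import FundusImage, write_image, write_mask

# phantom palette (RGB, uint8 scale)
_RETINA_COLOR = np.array([190.0, 88.0, 36.0])
_DISC_COLOR = np.array([232.0, 190.0, 118.0])
_CUP_COLOR = np.array([250.0, 226.0, 170.0])
_VESSEL_COLOR = np.array([120.0, 28.0, 18.0])

# horizontal/vertical axis ratio of the rendered disc: real optic discs are
# slightly vertically oval.
_DISC_ASPECT = 0.90

# VCDR severity model for cohorts: Beta distributions keep values in [0, 1];
# glaucomatous eyes cup more (mean ~0.70) than healthy eyes (mean ~0.30).
BETA_POSITIVE = (8.0, 3.5)
BETA_NEGATIVE = (3.5, 8.0)
# probability that the fellow eye of a glaucomatous participant is also
# affected (glaucomatous damage is frequently unilateral)
_BILATERAL_PROB = 0.5


@dataclass
class PhantomSpec:
    """Parameters of one synthetic fundus image.

    disc_ratio is the vertical disc extent as a fraction of image height
    (the 30-degree disc-centered reference value is 0.23; 45-degree
    macula-centered captures sit near 0.15). vcdr is the vertical cup-disc
    ratio in [0, 1]. illumination_amplitude is the peak relative deviation
    of the multiplicative lighting gradient (0 = perfectly even lighting).
    Coordinates are 0-based (row, col); extents are inclusive pixel counts.
    """

    image_height: int = 512
    image_width: int = 512
    fov_degrees: float = 30.0
    disc_ratio: float = 0.23
    vcdr: float = 0.3
    disc_center: tuple[float, float] | None = None
    vessel_count: int = 6
    illumination_amplitude: float = 0.15
    label: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 64:
            raise ValueError(f"image_height must be >= 64, got {self.image_height}")
        if self.image_width < 64:
            raise ValueError(f"image_width must be >= 64, got {self.image_width}")
        if not 0.0 < self.disc_ratio < 1.0:
            raise ValueError(f"disc_ratio must lie in (0, 1), got {self.disc_ratio}")
        if not 0.0 <= self.vcdr <= 1.0:
            raise ValueError(f"vcdr must lie in [0, 1], got {self.vcdr}")
        if self.vessel_count < 0:
            raise ValueError(f"vessel_count must be >= 0, got {self.vessel_count}")
        if self.illumination_amplitude < 0:
            raise ValueError(
                f"illumination_amplitude must be >= 0, got {self.illumination_amplitude}"
            )
        if self.fov_degrees <= 0:
            raise ValueError(f"fov_degrees must be > 0, got {self.fov_degrees}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def center(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return tuple(self.disc_center)
        return (self.image_height / 2.0, self.image_width / 2.0)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if d["disc_center"] is not None:
            d["disc_center"] = list(d["disc_center"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("disc_center") is not None:
            d["disc_center"] = tuple(d["disc_center"])
        return cls(**d)


@dataclass
class PhantomBundle:
    """A rendered phantom: image plus ground-truth disc and cup masks."""

    image: FundusImage
    disc_mask: np.ndarray
    cup_mask: np.ndarray
    spec: PhantomSpec

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = self.image.image_id or "phantom"
        write_image(directory / f"{stem}.png", self.image)
        write_mask(directory / f"{stem}_disc.png", self.disc_mask)
        write_mask(directory / f"{stem}_cup.png", self.cup_mask)
        self.spec.to_yaml(directory / f"{stem}.yaml")


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    v_extent: int,
    aspect: float = _DISC_ASPECT,
) -> np.ndarray:
    """Filled ellipse whose vertical bounding-box extent is exactly v_extent px.

    With an integer-rounded center the semi-axis (E-1)/2 covers exactly E rows
    for odd E; for even E the center is shifted half a pixel so the row count
    stays exact.
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if v_extent <= 0:
        return mask
    r0, c0 = int(round(center[0])), int(round(center[1]))
    if v_extent == 1:
        if 0 <= r0 < h and 0 <= c0 < w:
            mask[r0, c0] = True
        return mask
    rc = float(r0) if v_extent % 2 == 1 else r0 - 0.5
    b = (v_extent - 1) / 2.0
    a = max(b * aspect, 0.51)
    h_extent = int(round(v_extent * aspect))
    cc = float(c0) if h_extent % 2 == 1 else c0 - 0.5
    # row-wise spans guarantee every row in [rc-b, rc+b] contains >= 1 pixel,
    # so the rendered vertical extent is exact
    r_lo = int(np.ceil(rc - b))
    r_hi = int(np.floor(rc + b))
    cols = np.arange(w)
    for r in range(max(r_lo, 0), min(r_hi, h - 1) + 1):
        t = (r - rc) / b
        half_w = max(a * np.sqrt(max(1.0 - t * t, 0.0)), 0.51)
        mask[r, np.abs(cols - cc) <= half_w] = True
    return mask


def _aperture_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    radius = 0.48 * min(h, w)
    rows = np.arange(h)[:, None] - (h - 1) / 2.0
    cols = np.arange(w)[None, :] - (w - 1) / 2.0
    return rows**2 + cols**2 <= radius**2


def _draw_vessels(
    canvas: np.ndarray,
    center: tuple[float, float],
    count: int,
    rng: np.random.Generator,
    disc_extent: int,
) -> None:
    """Dark random-walk polylines emanating from the disc center (in place)."""
    h, w = canvas.shape[:2]
    thickness = max(1, h // 256)
    step = max(2, h // 128)
    n_steps = int(0.45 * min(h, w) / step)
    for k in range(count):
        angle = rng.uniform(0, 2 * np.pi)
        r, c = float(center[0]), float(center[1])
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.25)
            r += step * np.sin(angle)
            c += step * np.cos(angle)
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w):
                break
            r_lo, r_hi = max(ri - thickness, 0), min(ri + thickness + 1, h)
            c_lo, c_hi = max(ci - thickness, 0), min(ci + thickness + 1, w)
            canvas[r_lo:r_hi, c_lo:c_hi] = _VESSEL_COLOR


def _illumination_field(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative gradient 1 + amplitude * plane, |plane| <= 1."""
    h, w = shape
    theta = rng.uniform(0, 2 * np.pi)
    rows = np.arange(h)[:, None] - (h - 1) / 2.0
    cols = np.arange(w)[None, :] - (w - 1) / 2.0
    plane = np.cos(theta) * cols + np.sin(theta) * rows
    peak = np.abs(plane).max()
    if peak > 0:
        plane = plane / peak
    return 1.0 + amplitude * plane


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render one phantom deterministically from its spec.

    The disc mask's vertical extent equals round(disc_ratio * image_height)
    within one pixel, the cup's extent equals vcdr times the disc extent
    within rasterization error, and identical (spec, seed) pairs produce
    byte-identical images.
    """
    spec.validate()
    h, w = spec.image_height, spec.image_width
    rng = derive_rng(spec.seed, "phantom")
    center = spec.center

    disc_extent = int(round(spec.disc_ratio * h))
    disc_extent = max(disc_extent, 1)
    disc_mask = _ellipse_mask((h, w), center, disc_extent)

    if spec.vcdr >= 1.0:
        cup_mask = disc_mask.copy()
    else:
        cup_extent = int(round(spec.vcdr * disc_extent))
        cup_extent = min(cup_extent, max(disc_extent - 2, 0))
        cup_mask = _ellipse_mask((h, w), center, cup_extent)
        cup_mask &= disc_mask

    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = _RETINA_COLOR
    canvas += rng.normal(0.0, 3.0, size=canvas.shape)
    canvas[disc_mask] = _DISC_COLOR
    canvas[cup_mask] = _CUP_COLOR
    _draw_vessels(canvas, center, spec.vessel_count, rng, disc_extent)

    field = _illumination_field((h, w), spec.illumination_amplitude, rng)
    canvas *= field[:, :, None]

    aperture = _aperture_mask((h, w))
    canvas[~aperture] = 0.0

    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    image = FundusImage(pixels=pixels, fov_degrees=spec.fov_degrees)
    return PhantomBundle(image=image, disc_mask=disc_mask, cup_mask=cup_mask, spec=spec)


def _draw_vcdr(positive: bool, rng: np.random.Generator) -> float:
    a, b = BETA_POSITIVE if positive else BETA_NEGATIVE
    return float(np.clip(rng.beta(a, b), 0.02, 0.98))


def generate_cohort(
    n_participants: int,
    prevalence: float,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
    missing_eye_rate: float = 0.0,
    disc_ratio_jitter: float = 0.015,
) -> tuple[list[PhantomBundle], pd.DataFrame]:
    """Simulate a screening cohort of two-eyed participants.

    Exactly round(prevalence * n_participants) participants are labelled
    glaucomatous. Each glaucomatous participant has at least one eye with
    VCDR drawn from the elevated Beta severity distribution; the fellow eye
    is affected with probability 0.5. Per-eye disc ratios are jittered
    around the template value to retain the natural heterogeneity in optic
    disc size. Returns the rendered bundles and a label table with columns
    image_id, participant_id, eye, label, vcdr.
    """
    if n_participants < 1:
        raise ValueError(f"n_participants must be >= 1, got {n_participants}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence}")
    if not 0.0 <= missing_eye_rate < 1.0:
        raise ValueError(f"missing_eye_rate must lie in [0, 1), got {missing_eye_rate}")
    template = spec_template or PhantomSpec()
    template.validate()

    n_pos = int(np.floor(prevalence * n_participants + 0.5))
    label_rng = derive_rng(seed, "labels")
    labels = np.zeros(n_participants, dtype=int)
    labels[label_rng.permutation(n_participants)[:n_pos]] = 1

    bundles: list[PhantomBundle] = []
    rows = []
    for idx in range(n_participants):
        pid = f"P{idx:04d}"
        p_rng = derive_rng(seed, "participant", idx)
        is_pos = bool(labels[idx])
        eyes = ["L", "R"]
        if missing_eye_rate > 0 and p_rng.uniform() < missing_eye_rate:
            eyes = [eyes[int(p_rng.integers(2))]]
        # the first listed eye of a positive participant is always affected
        affected = {eyes[0]: is_pos}
        for eye in eyes[1:]:
            affected[eye] = is_pos and (p_rng.uniform() < _BILATERAL_PROB)
        for eye in eyes:
            vcdr = _draw_vcdr(affected[eye], p_rng)
            ratio = float(
                np.clip(
                    template.disc_ratio + p_rng.normal(0.0, disc_ratio_jitter),
                    0.05,
                    0.60,
                )
            )
            eye_spec = replace(
                template,
                vcdr=vcdr,
                disc_ratio=ratio,
                label=int(is_pos),
                seed=int(derive_rng(seed, "eye-seed", idx, eye).integers(2**31)),
            )
            bundle = generate_phantom(eye_spec)
            image_id = f"{pid}_{eye}"
            bundle.image.image_id = image_id
            bundle.image.participant_id = pid
            bundle.image.eye = eye
            bundles.append(bundle)
            rows.append(
                {
                    "image_id": image_id,
                    "participant_id": pid,
                    "eye": eye,
                    "label": int(is_pos),
                    "vcdr": vcdr,
                }
            )
    table = pd.DataFrame(rows, columns=["image_id", "participant_id", "eye", "label", "vcdr"])
    return bundles, table


def write_cohort(
    bundles: list[PhantomBundle], table: pd.DataFrame, directory: str | Path
) -> None:
    """Write images/masks as PNG and the label table as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for bundle in bundles:
        bundle.write(directory)
    table.to_csv(directory / "labels.csv", index=False)
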