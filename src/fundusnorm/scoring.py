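"""Continuous glaucoma risk scorers and the scored-record container.

A risk scorer maps one eye's data to a score in [0, 1]. Any trained model
can be plugged in through the :class:`Scorer` interface; the package ships
two reference scorers that stand in for a trained network when testing the
evaluation machinery:

* :class:`MaskVCDRScorer` measures the vertical cup-disc ratio (VCDR) from
  segmentation masks — the classical structural glaucoma biomarker;
* :class:`NoisyOracleScorer` perturbs the ground-truth VCDR with Gaussian
  noise of known sigma, giving a scorer of controllable discrimination.

Scored eyes are exchanged as a flat table (one row per image) so that users
with real model outputs can run the evaluation directly from a CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fundusnorm._rng import derive_rng
from fundusnorm.phantom import PhantomBundle

SCORE_COLUMNS = ["image_id", "participant_id", "eye", "score", "label"]


@dataclass
class RiskRecord:
    """One scored eye: continuous risk in [0, 1] plus the reference label."""

    image_id: str
    participant_id: str
    eye: str
    score: float
    label: int
    vcdr_measured: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.vcdr_measured is not None and not 0.0 <= self.vcdr_measured <= 1.0:
            raise ValueError(f"vcdr must lie in [0, 1], got {self.vcdr_measured}")


def _vertical_extent(mask: np.ndarray) -> int:
    rows = np.nonzero(np.any(mask, axis=1))[0]
    if rows.size == 0:
        return 0
    return int(rows[-1] - rows[0] + 1)


def vcdr_from_masks(disc_mask: np.ndarray, cup_mask: np.ndarray) -> float:
    """Vertical cup-disc ratio from segmentation masks.

    Both extents are tight bounding-box heights. A cup extending beyond the
    disc is intersected with it (with a warning) before measuring.
    """
    disc = np.asarray(disc_mask, dtype=bool)
    cup = np.asarray(cup_mask, dtype=bool)
    if not disc.any():
        raise ValueError("disc mask is empty")
    if (cup & ~disc).any():
        warnings.warn("cup mask extends outside disc mask; intersecting", stacklevel=2)
        cup = cup & disc
    if not cup.any():
        return 0.0
    return _vertical_extent(cup) / _vertical_extent(disc)


class Scorer:
    """Pluggable risk-scorer contract: bundle in, score in [0, 1] out."""

    name: str = "scorer"
    deterministic: bool = True

    def score(self, bundle: PhantomBundle) -> float:
        raise NotImplementedError

    def __call__(self, bundle: PhantomBundle) -> float:
        return float(np.clip(self.score(bundle), 0.0, 1.0))


class MaskVCDRScorer(Scorer):
    """Score = VCDR measured from the bundle's segmentation masks."""

    name = "mask_vcdr"
    deterministic = True

    def score(self, bundle: PhantomBundle) -> float:
        return vcdr_from_masks(bundle.disc_mask, bundle.cup_mask)


class NoisyOracleScorer(Scorer):
    """Ground-truth VCDR plus Gaussian noise of standard deviation sigma.

    sigma = 0 gives a perfect monotone scorer (downstream AUC 1 whenever the
    class VCDR ranges are disjoint); large sigma degrades discrimination
    toward chance. Noise is keyed per image id so scores do not depend on
    evaluation order.
    """

    name = "noisy_oracle"
    deterministic = True  # fixed seed => reproducible

    def __init__(self, sigma: float = 0.1, seed: int = 0) -> None:
        if sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {sigma}")
        self.sigma = sigma
        self.seed = seed

    def score(self, bundle: PhantomBundle) -> float:
        true_vcdr = bundle.spec.vcdr
        if self.sigma == 0:
            return true_vcdr
        rng = derive_rng(self.seed, "noisy-oracle", bundle.image.image_id)
        return true_vcdr + rng.normal(0.0, self.sigma)


def get_scorer(name: str, sigma: float = 0.1, seed: int = 0) -> Scorer:
    if name == "mask_vcdr":
        return MaskVCDRScorer()
    if name == "noisy_oracle":
        return NoisyOracleScorer(sigma=sigma, seed=seed)
    raise ValueError(f"unknown scorer {name!r}")


def score_cohort(bundles: list[PhantomBundle], scorer: Scorer) -> pd.DataFrame:
    """Score every bundle; returns one row per eye.

    Columns: image_id, participant_id, eye, score, label, vcdr (measured
    from the ground-truth masks).
    """
    rows = []
    for bundle in bundles:
        rows.append(
            {
                "image_id": bundle.image.image_id,
                "participant_id": bundle.image.participant_id,
                "eye": bundle.image.eye,
                "score": scorer(bundle),
                "label": int(bundle.spec.label),
                "vcdr": vcdr_from_masks(bundle.disc_mask, bundle.cup_mask),
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS + ["vcdr"])


def write_scores_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"scores file is missing required columns: {missing}")
    if not frame["score"].between(0, 1).all():
        raise ValueError("scores must lie in [0, 1]")
    if not frame["label"].isin([0, 1]).all():
        raise ValueError("labels must be 0 or 1")
    return frame
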