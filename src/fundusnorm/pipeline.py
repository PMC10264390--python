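"""End-to-end orchestration: phantoms -> QC -> FOV normalization ->
illumination correction -> scoring -> evaluation.

Every stage consumes the previous stage's survivors and logs the images it
discards, so records are conserved: each image entering a stage appears in
its output or in the discard log. One top-level seed drives everything;
per-stage streams are derived by stable hashing of the stage name, so reruns
with the same config reproduce deterministic-stage outputs byte-identically
(the manifest records checksums to prove it).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fundusnorm import __version__
from fundusnorm._rng import derive_rng
from fundusnorm.phantom import PhantomSpec, generate_cohort
from fundusnorm.qc import qc_dataset
from fundusnorm.fovnorm import (
    build_disc_ratio_table,
    plan_crop,
    crop_disc_centered,
    extend_to_30,
    blackout_synthetic,
    REFERENCE_DISC_RATIO,
)
from fundusnorm.illumination import CorrectionParams, correct_illumination, finalize_input
from fundusnorm.scoring import get_scorer, score_cohort, write_scores_csv
from fundusnorm.evaluate import evaluate_cohort, plot_report, DEFAULT_SPEC_TARGETS


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; unknown YAML keys are rejected."""

    seed: int = 0
    # fixtures
    n_participants: int = 40
    prevalence: float = 0.25
    image_size: int = 512
    fov_degrees: float = 30.0
    disc_ratio: float = 0.23
    vessel_count: int = 6
    illumination_amplitude: float = 0.15
    missing_eye_rate: float = 0.0
    # stages
    run_qc: bool = True
    transform_mode: str = "standard_grouped"
    fixed_crop_factor: float = 0.65
    output_size: int = 512
    illumination_sigma_frac: float = 0.05
    illumination_mode: str = "divide"
    scorer: str = "noisy_oracle"
    scorer_sigma: float = 0.10
    fixed_tv: float = 0.7
    spec_targets: tuple[float, ...] = DEFAULT_SPEC_TARGETS
    calibration_bins: int = 10
    participant_level: bool = True
    write_images: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "spec_targets" in data:
            data["spec_targets"] = tuple(data["spec_targets"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["spec_targets"] = list(d["spec_targets"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(arrays: list[np.ndarray]) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    bundles: list | None = None,
    labels: pd.DataFrame | None = None,
) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    Pre-built phantom bundles (with their label table) may be supplied to
    bypass fixture generation, e.g. to QC a constructed set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config))),
        "stages": {},
        "checksums": {},
        "discards": [],
    }

    # ---- fixtures -------------------------------------------------------
    template = PhantomSpec(
        image_height=config.image_size,
        image_width=config.image_size,
        fov_degrees=config.fov_degrees,
        disc_ratio=config.disc_ratio,
        vessel_count=config.vessel_count,
        illumination_amplitude=config.illumination_amplitude,
    )
    if bundles is None:
        fixture_seed = int(derive_rng(config.seed, "fixtures").integers(2**31))
        bundles, labels = generate_cohort(
            config.n_participants,
            config.prevalence,
            template,
            seed=fixture_seed,
            missing_eye_rate=config.missing_eye_rate,
        )
    elif labels is None:
        raise ValueError("labels table required when bundles are supplied")
    labels.to_csv(outdir / "labels.csv", index=False)
    manifest["stages"]["fixtures"] = {
        "images_out": len(bundles),
        "participants": config.n_participants,
        "positives": int(labels.groupby("participant_id")["label"].max().sum()),
    }
    manifest["checksums"]["fixtures"] = _sha256([b.image.pixels for b in bundles])
    if config.write_images:
        img_dir = outdir / "images"
        for b in bundles:
            b.write(img_dir)

    # ---- qc -------------------------------------------------------------
    by_id = {b.image.image_id: b for b in bundles}
    if config.run_qc:
        report = qc_dataset([b.image for b in bundles])
        report.to_csv(outdir / "qc.csv")
        kept_ids = [r.image_id for r in report.kept()]
        detections = {
            r.image_id: r.detection for r in report.results if r.status == "kept"
        }
        for r in report.results:
            if r.status == "discarded":
                manifest["discards"].append(
                    {"stage": "qc", "image_id": r.image_id, "reason": r.reason}
                )
        manifest["stages"]["qc"] = {
            "images_in": report.n_total,
            "images_out": report.n_kept,
            "removal_rate_percent": report.removal_rate,
        }
    else:
        kept_ids = list(by_id)
        from fundusnorm.qc import detection_from_mask

        detections = {
            iid: detection_from_mask(by_id[iid].disc_mask) for iid in kept_ids
        }
        manifest["stages"]["qc"] = {
            "images_in": len(bundles),
            "images_out": len(bundles),
            "removal_rate_percent": 0.0,
            "skipped": True,
        }

    if not kept_ids:
        raise RuntimeError("stage qc: all images were discarded")

    # ---- transform ------------------------------------------------------
    table = build_disc_ratio_table(
        [
            ((by_id[iid].image.height, by_id[iid].image.width), detections[iid].disc_ratio)
            for iid in kept_ids
        ]
    )
    rng = derive_rng(config.seed, "transform")
    transformed: dict[str, tuple] = {}
    plans_log = []
    for iid in kept_ids:
        bundle = by_id[iid]
        det = detections[iid]
        if det.disc_ratio > REFERENCE_DISC_RATIO and config.transform_mode == "extend":
            img, plan = extend_to_30(bundle.image, det)
        else:
            plan = plan_crop(
                det,
                (bundle.image.height, bundle.image.width),
                mode=config.transform_mode,
                table=table,
                fixed_factor=config.fixed_crop_factor,
                rng=rng,
                output_size=config.output_size,
            )
            img, plan = crop_disc_centered(bundle.image, det, plan)
        transformed[iid] = (img, plan)
        plans_log.append(plan.to_json())
    (outdir / "plans.jsonl").write_text("\n".join(plans_log) + "\n")
    manifest["stages"]["transform"] = {
        "images_in": len(kept_ids),
        "images_out": len(transformed),
        "mode": config.transform_mode,
    }
    manifest["checksums"]["transform"] = _sha256(
        [transformed[iid][0].pixels for iid in kept_ids]
    )

    # ---- illumination correction + finalize ------------------------------
    params = CorrectionParams(
        sigma_frac=config.illumination_sigma_frac, mode=config.illumination_mode
    )
    finalized: dict[str, np.ndarray] = {}
    for iid in kept_ids:
        img, plan = transformed[iid]
        corrected = correct_illumination(img, params)
        if plan.extension_record is not None:
            corrected = blackout_synthetic(corrected, plan)
        finalized[iid] = finalize_input(corrected, size=config.output_size)
    manifest["stages"]["correct"] = {
        "images_in": len(kept_ids),
        "images_out": len(finalized),
    }
    manifest["checksums"]["correct"] = _sha256(list(finalized.values()))

    # ---- scoring ---------------------------------------------------------
    scorer_seed = int(derive_rng(config.seed, "scoring").integers(2**31))
    scorer = get_scorer(config.scorer, sigma=config.scorer_sigma, seed=scorer_seed)
    kept_bundles = [by_id[iid] for iid in kept_ids]
    records = score_cohort(kept_bundles, scorer)
    write_scores_csv(records, outdir / "scores.csv")
    manifest["stages"]["score"] = {
        "images_in": len(kept_ids),
        "records_out": len(records),
        "scorer": scorer.name,
    }
    manifest["checksums"]["score"] = hashlib.sha256(
        records.to_csv(index=False).encode()
    ).hexdigest()

    # ---- evaluation ------------------------------------------------------
    eye_report = evaluate_cohort(
        records,
        level="eye",
        tv=config.fixed_tv,
        spec_targets=config.spec_targets,
        bins=config.calibration_bins,
        compare_vcdr=True,
    )
    eye_report.to_json(outdir / "eval_eye.json")
    eye_report.calibration.to_csv(outdir / "calibration_eye.csv", index=False)
    eye_report.operating_points_frame().to_csv(
        outdir / "operating_points_eye.csv", index=False
    )
    plot_report(
        eye_report,
        records["score"].to_numpy(),
        records["label"].to_numpy(),
        outdir / "eval_eye.png",
    )
    manifest["stages"]["evaluate"] = {
        "records_in": len(records),
        "auc_eye": eye_report.auc,
    }
    if config.participant_level:
        part_report = evaluate_cohort(
            records,
            level="participant",
            tv=config.fixed_tv,
            spec_targets=config.spec_targets,
            bins=config.calibration_bins,
            compare_vcdr=True,
        )
        part_report.to_json(outdir / "eval_participant.json")
        manifest["stages"]["evaluate"]["auc_participant"] = part_report.auc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
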