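# fundusnorm

Standardization of heterogeneous color fundus photographs to 30° optic-disc-centered
model inputs, and threshold/ROC evaluation of continuous glaucoma risk scores.

Glaucoma screening models are typically trained on one camera setup — e.g. 30°
disc-centered photographs — and then confronted with external data captured at 45°
macula-centered, at smaller fields of view (FOV), or pre-cropped around the optic
nerve head (ONH). `fundusnorm` implements the image-standardization pipeline that
removes this covariate shift, together with the complete evaluation machinery for a
continuous risk score, and a synthetic fundus *phantom* generator so the entire stack
is testable without any clinical data or a trained network.

## What it does

**Quality control (`fundusnorm.qc`).** Candidate disc segmentations are screened by
two realism criteria: the *disc ratio* (vertical disc extent / image height) must lie
in [0.10, 0.40] for ≥30° captures, and among survivors the component whose first Hu
invariant moment η₂₀ + η₀₂ is closest to the perfect-circle value 1/(2π) ≈ 0.159 is
selected, discarding oblong artifacts. Images with no admissible candidate are
discarded; the report tracks the removal rate. Trusted ground-truth masks bypass
screening.

**FOV normalization (`fundusnorm.fovnorm`).** Images with FOV above 30° are cropped
to a square window around the disc with

```
crop factor = disc_ratio_original / disc_ratio_30°,   disc_ratio_30° = 0.23
```

so a 45° capture (disc ratio ≈ 0.15) gets a factor of ≈ 0.65. Disc ratios are
averaged per image size (sizes with < 10 cases fall back to the global mean) so a
uniform factor per size group preserves natural disc-size heterogeneity. Windows
overrunning the frame are zero-padded. Sub-30° or pre-cropped inputs are instead
*extended* by border replication until the disc ratio reaches 0.23; the replicated
frame is blacked out after illumination correction. Sensitivity-analysis modes are
included: fixed factor (0.65), random factor in [0.40, 0.80], per-image disc
rescaling to 0.23, and passthrough resizing.

**Illumination correction (`fundusnorm.illumination`).** A per-channel background is
estimated by aperture-masked Gaussian smoothing and divided out
(mean-preserving), flattening the smooth lighting gradients caused by retinal
curvature. Final model inputs are 512×512×3 arrays scaled to [0, 1].

**Scoring (`fundusnorm.scoring`).** A pluggable scorer contract maps an eye to a
risk score in [0, 1]. Shipped reference scorers: the vertical cup-disc ratio (VCDR)
measured from segmentation masks, and a noisy oracle (true VCDR + Gaussian noise)
with controllable discrimination. Real model outputs can be supplied as a CSV.

**Evaluation (`fundusnorm.evaluate`).** Rank-based AUC with midrank ties, fast
DeLong 95% confidence intervals, the balanced operating point (min |sens − spec|),
sensitivities at 90/95/97.5% specificity, the fixed threshold TV = 0.7 (a common
VCDR referral cut) with Wilson CIs, participant-level aggregation (max risk over
eyes), 10-bin calibration curves, prediction histograms, Cohen's κ for categorical
grader agreement, Pearson associations with clinical covariates, and a paired
score-vs-VCDR AUC comparison.

**Phantoms (`fundusnorm.phantom`).** Seeded synthetic fundus images — a bright
elliptical disc with a nested cup of exact VCDR, dark vessels, a circular aperture
and a multiplicative illumination gradient — plus screening cohorts with two eyes
per participant and Beta-distributed VCDR severity per class. All geometry is exact
by construction, giving ground truth for every stage.

## Worked example

```python
from fundusnorm.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=42, n_participants=30, prevalence=0.3, image_size=256)
manifest = run_pipeline(cfg, "scratch/demo")
print(manifest["stages"]["evaluate"])
```

prints

```
{'records_in': 60, 'auc_eye': 0.794973544973545, 'auc_participant': 0.8994708994708994}
```

60 phantom eyes (30 participants, 9 glaucomatous) pass QC, are cropped to the 30°
standard via the grouped disc-ratio table, illumination-corrected, and scored by the
noisy VCDR oracle (σ = 0.10). Eye-level AUC is 0.795 — fellow eyes of glaucomatous
participants are often unaffected, diluting eye-level discrimination — while the
participant-level AUC (max of the two eyes, mimicking expert referral) rises to
0.899 [95% CI 0.792–1.000]. The balanced operating point lands at threshold 0.614
(sensitivity 0.778, specificity 0.810); the fixed VCDR-style cut 0.7 trades
sensitivity (0.556) for specificity (0.857). `scratch/demo/` holds the label table,
QC report, transform plans, scores CSV, evaluation JSON and the ROC/calibration/
histogram figure.

The same stages are available from the shell:

```
fundusnorm fixtures --out data --n 30 --prevalence 0.3 --seed 42
fundusnorm qc data --out qc_out
fundusnorm run --out run_out --seed 42
```

## Layout

- `src/fundusnorm/` — library modules (`phantom`, `qc`, `fovnorm`, `illumination`,
  `scoring`, `evaluate`, `pipeline`, `cli`)
- `tests/` — pytest suite with brute-force oracles for every statistic
- `docs/methods.md` — models, assumptions, parameter choices and limitations
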