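# Methods

## Problem setting

A continuous glaucoma risk score (for instance a regression CNN trained on
30° disc-centered photographs with expert VCDR as a soft label) must be
evaluated on external datasets whose images differ in field of view, disc
position, lighting and cropping. `fundusnorm` standardizes such images to
the 30° disc-centered geometry the scorer expects and evaluates the scores
against a binary reference standard. The trained scorer itself is out of
scope; the package treats it as a pluggable function and ships synthetic
stand-ins so the full chain is testable.

## Phantom model

A phantom is the minimal image that exercises every measurement the
pipeline makes:

- retina: constant orange background (RGB ≈ 190/88/36) with Gaussian pixel
  noise (σ = 3 intensity levels) inside a circular aperture of radius
  0.48·min(H, W); outside is black, as in real fundus photographs;
- optic disc: bright ellipse, horizontal/vertical axis ratio 0.90 (real
  discs are slightly vertically oval). The ellipse is rasterized row-wise
  so its vertical bounding-box extent equals round(disc_ratio · H)
  *exactly*; coordinates are 0-based (row, col) and extents are inclusive
  pixel counts throughout the package;
- cup: brighter concentric ellipse with vertical extent round(vcdr ·
  disc_extent), capped at disc_extent − 2 for vcdr < 1 so the cup stays
  strictly inside the disc (at vcdr = 1 the cup degenerates to the disc);
- vessels: dark random-walk polylines (step H/128, angular jitter σ = 0.25
  rad) radiating from the disc center — enough texture to stress the
  threshold segmenter without photorealism;
- illumination: a multiplicative tilted plane 1 + A·f, |f| ≤ 1, with random
  orientation; A is the peak relative deviation (default 0.15, a moderate
  gradient; 0 disables it).

All randomness derives from one integer seed through counter-based
splitting (`numpy` SeedSequence keyed by CRC32-hashed labels), so per-image
streams are independent of generation order and identical (spec, seed)
pairs are byte-identical.

**Cohorts.** Participants have two eyes (optionally one, controlled by a
missing-eye rate); exactly round(prevalence · n) participants are positive.
VCDR severity is Beta-distributed per class — positives Beta(8, 3.5) (mean
≈ 0.70), negatives Beta(3.5, 8) (mean ≈ 0.30), clipped to [0.02, 0.98].
These defaults give realistic overlap: structural VCDR separates glaucoma
well but not perfectly. A positive participant always has at least one
affected eye; the fellow eye is affected with probability 0.5, reflecting
frequently unilateral disease. Per-eye disc ratios are jittered (σ = 0.015)
around the template to retain natural disc-size heterogeneity.

What phantoms do **not** model: media opacities, pallor/rim color cues,
peripapillary atrophy, camera color profiles, non-planar illumination
fields, or any pathology other than cupping. Passing tests therefore
validate the *geometry and statistics* of the pipeline, not clinical
performance on real photographs.

## Quality control

The vertical optic-disc size of a candidate component is the height of its
tight bounding box (the simplest reading; no sub-pixel fitting). The
screening criteria are: disc ratio within [0.10, 0.40] (applied only to
images declaring FOV ≥ 30°, since the bounds are FOV-conditional; sub-30°
inputs take the largest component unscreened), then argmin |η₂₀ + η₀₂ −
1/(2π)| among survivors. The Hu invariant is computed on the binary mask;
the circle constant is stored at full precision 1/(2π) and compared to the
printed 0.159 only in tests. Ties in the argmin are broken by larger
component area, then lower component id, for determinism.

The stand-in segmenter (`segment_disc_simple`) is deliberately simple: Otsu
threshold of the mean-channel intensity inside the aperture, morphological
closing (disk radius ≈ H/170) plus hole filling to survive vessel
crossings, connected components ≥ 0.02% of the frame. It recovers phantom
discs with IoU > 0.9 and exists only so the pipeline runs without a
segmentation model; user-supplied masks always take precedence.

## FOV normalization

The crop window is square with side round(crop_factor · H), centered on the
detected disc centroid; the window is clipped against the frame and the
out-of-bounds remainder zero-padded, then resized to 512² (bilinear for
images, nearest-neighbor for masks). Width reuses the height-derived side
because the output is square. Nominal output FOV = source FOV × crop
factor (45° × 0.65 ≈ 30°; 45° × 0.40 = 18°).

Extension for sub-30° inputs replicates the border (edge replication, not
reflection) symmetrically per axis until new_height = round(extent / 0.23);
width grows in proportion to preserve aspect ratio, and odd remainders go
to the bottom/right edge. The per-edge replication widths are recorded so
the synthetic frame can be blacked out *after* illumination correction —
the replicated pixels support the background estimate but never reach the
scorer.

The grouped disc-ratio table averages per (height, width) and falls back to
the global mean below 10 cases per size. Alternative modes — fixed factor,
uniform random factor on [0.40, 0.80], per-image rescaling to 0.23,
passthrough resize — share the same window machinery.

## Illumination correction

Background per channel: Gaussian smoothing restricted to the aperture by
normalized convolution, `bg = G(img·m) / G(m)` with m the in-aperture mask
(mean intensity > 5); a plain blur would drag the estimate toward zero near
the rim and create halos. Divide mode computes img/bg and rescales to
preserve the in-aperture channel mean; subtract mode removes bg and
restores the mean. Outputs are clipped to [0, 255]; black exterior pixels
remain black under division.

Default sigma is 0.05 × image height (≈ H/20). This follows common fundus
shade-correction practice (background kernels of roughly width/20–width/30)
and is the scale at which a whole-aperture gradient is actually cancelled:
measured on phantoms with a 0.3-amplitude gradient, residual correlation
with the injected field is ≈ 0.03 at sigma_frac 0.05 versus ≈ 0.9 at 0.25,
and one extra pass changes mean intensity by < 0.3% (near-idempotence).
Wider kernels are configurable but cannot track fields that vary over the
full aperture. Model inputs are finalized to 512×512×3 in [0, 1] (divide
by 255).

## Evaluation

- **AUC**: midrank-based, equal to P(s⁺ > s⁻) + ½P(tie); invariant under
  strictly monotone transforms.
- **DeLong interval**: structural components computed from class-wise and
  pooled midranks in O(n log n); variance var(V₁₀)/m + var(V₀₁)/n; normal
  interval clipped to [0, 1]. Perfect separation gives zero variance and a
  flagged degenerate interval. Coverage at n = 200 with the noisy-oracle
  score model measures ≈ 0.93–0.94, the expected mild anti-conservatism of
  the normal approximation at AUC ≈ 0.92.
- **Operating points**: positive call means score ≥ threshold (reading a
  VCDR cut of 0.7 as "0.7 or more is abnormal"); candidate thresholds are
  the distinct scores plus a sentinel above the maximum. The balanced point
  minimizes |sens − spec| with ties broken by max(sens + spec), then lowest
  threshold. Sensitivity-at-specificity uses the conservative step-function
  rule (specificity ≥ target, no ROC interpolation). Proportions at the
  fixed threshold get Wilson 95% intervals.
- **Participant aggregation**: score = max over available eyes; label = the
  provided participant-level reference, or the OR of eye labels when only
  eye labels exist (glaucoma can be unilateral).
- **Calibration**: 10 equal-width bins on [0, 1]; empty bins omitted;
  counts conserved. Scores of exactly 1.0 fall in the top bin.
- **Cohen's κ** operates on gradings binarized by a stated referable set
  ({definite} or {suspect, definite}); constant marginals yield NaN with a
  warning rather than a spurious 0.
- **Covariate association**: Pearson r with Fisher-z 95% CI, pairwise
  missing-value deletion.

## Pipeline and determinism

Stage order: fixtures → QC → transform → illumination correction (+
blackout of extension frames) → finalize → score → evaluate. Every stage's
input count equals its output count plus its discard-log entries. One
top-level seed is split per stage by stable label hashing; the manifest
records per-stage counts, the removal rate and SHA-256 checksums of the
deterministic stage outputs, so reruns with the same config are verifiably
byte-identical. Reference scorers consume ground-truth VCDR (mask-measured
or spec-level), not the corrected pixels; the image branch exists to be
standardized and checked, which is exactly what a real CNN scorer would
consume instead.

## Problem sizes used in the checks

Unit and property tests run on 128–512 px phantoms and cohorts of 5–30
participants; oracle-equivalence checks use 1000 randomized instances of
n ≤ 50 against O(n²) and exhaustive-scan references; DeLong coverage uses
500 cohorts of n = 200 against a long-run AUC estimated from one 10⁶-pair
draw; pipeline determinism runs the full chain twice at 192 px with 6–10
participants. These sizes were chosen so the whole suite exercises every
code path in well under a minute per module on a single CPU.

## Known limitations

- The threshold segmenter assumes the disc is the brightest large structure;
  strong rim reflections or bright lesions in real images would need a real
  segmentation model (supplied masks bypass it).
- The illumination model is a single multiplicative plane; real shading is
  radial/vignetting-like and channel-dependent, so sigma_frac may need
  retuning per camera.
- Border extension assumes the disc is roughly centered in sub-30° inputs;
  extreme off-center discs would change the ratio denominator asymmetrically.
- DeLong intervals undercover slightly below n ≈ 100 or at AUC near 1;
  the degenerate-interval flag marks the pathological cases but small-sample
  exact methods are not implemented.
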