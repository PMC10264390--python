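"""Threshold/ROC evaluation of continuous risk scores.

Implements the full screening-evaluation procedure for a continuous risk
score against a binary reference standard:

* rank-based AUC with midrank tie handling and fast DeLong 95% confidence
  intervals from structural components;
* the balanced operating point (minimal |sensitivity - specificity|),
  sensitivities at fixed specificity levels (90 / 95 / 97.5%), and the
  fixed decision threshold 0.7 (a common VCDR cut for glaucoma) with Wilson
  confidence intervals on the resulting proportions;
* participant-level aggregation taking the maximum predicted risk of the
  two eyes, mimicking expert referral;
* a 10-bin calibration curve, the prediction histogram, Cohen's kappa for
  categorical grader agreement, and Pearson associations between scores and
  clinical covariates;
* a paired comparison of the risk score against image-measured VCDR on the
  same cohort.

A positive call means score >= threshold throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

DEFAULT_SPEC_TARGETS = (0.90, 0.95, 0.975)
FIXED_TV = 0.7


def _validate_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("degenerate labels: both classes must be present")
    return scores, labels


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based); tied values share the average of their ranks."""
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels) -> float:
    """Rank-based AUC: P(score+ > score-) + 0.5 P(tie)."""
    scores, labels = _validate_binary(scores, labels)
    pos = scores[labels == 1]
    m = pos.size
    n = scores.size - m
    ranks = _midranks(scores)
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2.0) / (m * n))


@dataclass
class DelongResult:
    auc: float
    variance: float
    lo: float
    hi: float
    degenerate: bool


def delong_interval(scores, labels, level: float = 0.95) -> DelongResult:
    """Fast DeLong AUC variance and normal-approximation interval.

    The variance is assembled from the per-observation structural
    components; ranks are computed once per class and once pooled, giving
    O(n log n) cost. Perfect separation yields zero variance and a
    degenerate interval, which is flagged.
    """
    scores, labels = _validate_binary(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("at least two observations per class are required")
    tx = _midranks(pos)
    ty = _midranks(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    auc = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    v01 = (tz[:m] - tx) / n  # structural components of the positives
    v10 = 1.0 - (tz[m:] - ty) / m  # ... of the negatives
    var = float(np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    degenerate = se == 0.0
    if degenerate:
        warnings.warn(
            "zero DeLong variance (perfect or inverted separation); "
            "interval is degenerate",
            stacklevel=2,
        )
    return DelongResult(auc=auc, variance=var, lo=lo, hi=hi, degenerate=degenerate)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong confidence interval for the AUC, clipped to [0, 1]."""
    res = delong_interval(scores, labels, level=level)
    return res.lo, res.hi


@dataclass
class OperatingPoint:
    """A (threshold, sensitivity, specificity) triple on the ROC curve."""

    threshold: float
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    degenerate: bool = False


def _threshold_scan(scores, labels):
    """Sensitivity/specificity at every achievable cut (score >= t positive).

    Returns thresholds (ascending; includes a sentinel above the maximum
    score where nothing is called positive), sensitivities, specificities.
    """
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    m, n = pos.size, neg.size
    uniq = np.unique(scores)
    thresholds = np.append(uniq, uniq[-1] + 1.0)
    tp = m - np.searchsorted(pos, thresholds, side="left")
    fp = n - np.searchsorted(neg, thresholds, side="left")
    sens = tp / m
    spec = (n - fp) / n
    return thresholds, sens, spec


def balanced_operating_point(scores, labels) -> OperatingPoint:
    """Operating point minimizing |sensitivity - specificity|.

    Ties are broken by maximal sensitivity + specificity, then by the lowest
    threshold. If the best achievable point has sensitivity + specificity
    <= 1 (no discrimination), it is flagged degenerate.
    """
    scores, labels = _validate_binary(scores, labels)
    thresholds, sens, spec = _threshold_scan(scores, labels)
    diff = np.abs(sens - spec)
    best = np.lexsort((thresholds, -(sens + spec), diff))[0]
    return OperatingPoint(
        threshold=float(thresholds[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        degenerate=bool(sens[best] + spec[best] <= 1.0),
    )


def sensitivity_at_specificity(
    scores, labels, spec_targets=DEFAULT_SPEC_TARGETS
) -> dict[float, OperatingPoint]:
    """Maximum sensitivity among thresholds achieving each specificity level.

    Uses the conservative step-function rule (specificity >= target, no ROC
    interpolation). Returns the achieving operating point per target.
    """
    scores, labels = _validate_binary(scores, labels)
    thresholds, sens, spec = _threshold_scan(scores, labels)
    out: dict[float, OperatingPoint] = {}
    for target in spec_targets:
        ok = spec >= target
        idx = np.nonzero(ok)[0]
        # sens is non-increasing in threshold, so the first qualifying
        # (lowest) threshold attains the maximum sensitivity
        best = idx[np.argmax(sens[idx])]
        out[float(target)] = OperatingPoint(
            threshold=float(thresholds[best]),
            sensitivity=float(sens[best]),
            specificity=float(spec[best]),
        )
    return out


def fixed_threshold_point(scores, labels, tv: float = FIXED_TV) -> OperatingPoint:
    """Sensitivity/specificity at a fixed decision threshold with Wilson CIs.

    The default threshold 0.7 is the common VCDR cut for glaucoma referral.
    """
    if not 0.0 <= tv <= 1.0:
        raise ValueError(f"tv must lie in [0, 1], got {tv}")
    scores, labels = _validate_binary(scores, labels)
    calls = scores >= tv
    tp = int(np.sum(calls & (labels == 1)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    fp = int(np.sum(calls & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = proportion_confint(tp, tp + fn, alpha=0.05, method="wilson")
    spec_ci = proportion_confint(tn, tn + fp, alpha=0.05, method="wilson")
    return OperatingPoint(
        threshold=tv,
        sensitivity=float(sens),
        specificity=float(spec),
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
    )


def aggregate_to_participant(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse eye-level records to participants.

    The participant score is the maximum predicted risk over the available
    eyes (mimicking expert referral: one glaucomatous eye suffices). The
    participant label is the provided per-row label (constant within a
    participant when it encodes the participant-level reference) or the OR
    of eye labels otherwise; measured VCDR aggregates as the worse eye.
    """
    if "participant_id" not in frame.columns:
        raise ValueError("records need a participant_id column")
    agg = {"score": "max", "label": "max"}
    if "vcdr" in frame.columns:
        agg["vcdr"] = "max"
    out = frame.groupby("participant_id", as_index=False).agg(agg)
    out["n_eyes"] = frame.groupby("participant_id").size().values
    return out


def calibration_curve(scores, labels, bins: int = 10) -> pd.DataFrame:
    """Reliability table over equal-width score bins on [0, 1].

    Per nonempty bin: mean predicted value, observed positive fraction and
    count. Empty bins are omitted; counts sum to the number of records.
    """
    scores, labels = _validate_binary(scores, labels)
    if scores.size < bins:
        raise ValueError(f"need at least {bins} records for {bins} bins")
    idx = np.minimum((scores * bins).astype(int), bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        count = int(sel.sum())
        if count == 0:
            continue
        rows.append(
            {
                "bin_lo": b / bins,
                "bin_hi": (b + 1) / bins,
                "mean_predicted": float(scores[sel].mean()),
                "fraction_positive": float(labels[sel].mean()),
                "count": count,
            }
        )
    return pd.DataFrame(rows)


GRADE_CATEGORIES = ("no", "suspect", "definite")


def cohens_kappa(
    ratings_a, ratings_b, positive_classes: tuple[str, ...] = ("definite",)
) -> float:
    """Chance-corrected agreement on binarized categorical gradings.

    Categories (e.g. no / suspect / definite glaucoma) are binarized by
    membership in ``positive_classes`` — ("definite",) treats only definite
    cases as referable; ("suspect", "definite") refers suspects too. Returns
    (po - pe) / (1 - pe); NaN (with a warning) when a constant marginal
    makes chance agreement equal 1.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be 1-D arrays of equal length")
    if a.size == 0:
        raise ValueError("ratings are empty")
    pos = set(positive_classes)
    x = np.array([r in pos for r in a], dtype=int)
    y = np.array([r in pos for r in b], dtype=int)
    po = float(np.mean(x == y))
    px1, py1 = x.mean(), y.mean()
    pe = px1 * py1 + (1 - px1) * (1 - py1)
    if pe >= 1.0:
        warnings.warn("constant marginals: kappa is undefined", stacklevel=2)
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def covariate_association(
    frame: pd.DataFrame, covariate_cols: list[str], score_col: str = "score"
) -> pd.DataFrame:
    """Pearson correlation of the risk score with clinical covariates.

    Missing values are dropped pairwise; the 95% CI uses the Fisher
    z-transform. Returns one row per covariate: r, CI, n.
    """
    rows = []
    for col in covariate_cols:
        pair = frame[[score_col, col]].dropna()
        n = len(pair)
        if n < 3:
            raise ValueError(f"covariate {col!r} has fewer than 3 paired points")
        r = float(stats.pearsonr(pair[score_col], pair[col]).statistic)
        if abs(r) >= 1.0 or n <= 3:
            lo, hi = r, r
        else:
            z = np.arctanh(r)
            se = 1.0 / np.sqrt(n - 3)
            crit = stats.norm.ppf(0.975)
            lo, hi = float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))
        rows.append({"covariate": col, "r": r, "ci_lo": lo, "ci_hi": hi, "n": n})
    return pd.DataFrame(rows)


def compare_score_vs_vcdr(frame: pd.DataFrame) -> dict:
    """Paired AUC comparison: risk score versus image-measured VCDR.

    Both are evaluated as continuous markers on the same cohort; reports
    each AUC with its DeLong interval, the difference, and whether the
    intervals overlap.
    """
    if "vcdr" not in frame.columns or frame["vcdr"].isna().any():
        raise ValueError("records must carry a complete vcdr column")
    labels = frame["label"].to_numpy()
    score_res = delong_interval(frame["score"].to_numpy(), labels)
    vcdr_res = delong_interval(frame["vcdr"].to_numpy(), labels)
    return {
        "score": {"auc": score_res.auc, "ci95": (score_res.lo, score_res.hi)},
        "vcdr": {"auc": vcdr_res.auc, "ci95": (vcdr_res.lo, vcdr_res.hi)},
        "difference": score_res.auc - vcdr_res.auc,
        "ci_overlap": not (score_res.lo > vcdr_res.hi or vcdr_res.lo > score_res.hi),
    }


@dataclass
class EvalReport:
    """Complete evaluation of one cohort at one aggregation level."""

    n: int
    n_positive: int
    auc: float
    ci95: tuple[float, float]
    balanced_point: OperatingPoint
    sens_at_spec: dict[float, OperatingPoint]
    fixed_tv_point: OperatingPoint
    calibration: pd.DataFrame
    histogram: pd.DataFrame
    level: str = "eye"
    vcdr_comparison: dict | None = None

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "n": self.n,
            "n_positive": self.n_positive,
            "auc": self.auc,
            "ci95": list(self.ci95),
            "balanced_point": asdict(self.balanced_point),
            "sens_at_spec": {str(k): asdict(v) for k, v in self.sens_at_spec.items()},
            "fixed_tv_point": asdict(self.fixed_tv_point),
            "calibration": self.calibration.to_dict(orient="records"),
            "histogram": self.histogram.to_dict(orient="records"),
            "vcdr_comparison": self.vcdr_comparison,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def operating_points_frame(self) -> pd.DataFrame:
        """All reported operating points as one table (for CSV export)."""
        rows = [
            {"name": "balanced", **asdict(self.balanced_point)},
            {"name": f"fixed_tv_{self.fixed_tv_point.threshold:g}",
             **asdict(self.fixed_tv_point)},
        ]
        for target, op in sorted(self.sens_at_spec.items()):
            rows.append({"name": f"spec_ge_{target:g}", **asdict(op)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Evaluation ({self.level} level): n={self.n}, positives={self.n_positive}",
            f"  AUC {self.auc:.3f} [95% CI: {self.ci95[0]:.3f}-{self.ci95[1]:.3f}]",
            (
                f"  balanced point: sens {self.balanced_point.sensitivity:.3f} / "
                f"spec {self.balanced_point.specificity:.3f} "
                f"@ TV {self.balanced_point.threshold:.3f}"
            ),
        ]
        for target in sorted(self.sens_at_spec):
            op = self.sens_at_spec[target]
            lines.append(
                f"  sens @ spec>={target:.3f}: {op.sensitivity:.3f} (TV {op.threshold:.3f})"
            )
        ftv = self.fixed_tv_point
        lines.append(
            f"  fixed TV {ftv.threshold:.2f}: sens {ftv.sensitivity:.3f} "
            f"[{ftv.sensitivity_ci[0]:.3f}-{ftv.sensitivity_ci[1]:.3f}], "
            f"spec {ftv.specificity:.3f} "
            f"[{ftv.specificity_ci[0]:.3f}-{ftv.specificity_ci[1]:.3f}]"
        )
        if self.vcdr_comparison is not None:
            vc = self.vcdr_comparison
            lines.append(
                f"  VCDR baseline AUC {vc['vcdr']['auc']:.3f}; "
                f"score - VCDR difference {vc['difference']:+.3f}"
            )
        return "\n".join(lines)


def prediction_histogram(scores, bins: int = 20) -> pd.DataFrame:
    scores = np.asarray(scores, dtype=float)
    counts, edges = np.histogram(scores, bins=bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )


def evaluate_cohort(
    frame: pd.DataFrame,
    level: str = "eye",
    tv: float = FIXED_TV,
    spec_targets=DEFAULT_SPEC_TARGETS,
    bins: int = 10,
    compare_vcdr: bool = False,
) -> EvalReport:
    """Run the full evaluation on a scored-record table.

    ``level="participant"`` first takes the maximum risk over each
    participant's eyes. ``compare_vcdr=True`` additionally evaluates the
    measured VCDR as a baseline marker on the same cohort.
    """
    if level == "participant":
        frame = aggregate_to_participant(frame)
    elif level != "eye":
        raise ValueError(f"level must be 'eye' or 'participant', got {level!r}")
    scores = frame["score"].to_numpy(dtype=float)
    labels = frame["label"].to_numpy(dtype=int)
    res = delong_interval(scores, labels)
    report = EvalReport(
        n=len(frame),
        n_positive=int(labels.sum()),
        auc=res.auc,
        ci95=(res.lo, res.hi),
        balanced_point=balanced_operating_point(scores, labels),
        sens_at_spec=sensitivity_at_specificity(scores, labels, spec_targets),
        fixed_tv_point=fixed_threshold_point(scores, labels, tv),
        calibration=calibration_curve(scores, labels, bins=bins),
        histogram=prediction_histogram(scores),
        level=level,
        vcdr_comparison=compare_score_vs_vcdr(frame) if compare_vcdr else None,
    )
    return report


def plot_report(report: EvalReport, scores, labels, path: str | Path) -> None:
    """ROC curve, calibration curve and prediction histogram in one figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores, labels = _validate_binary(scores, labels)
    thresholds, sens, spec = _threshold_scan(scores, labels)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))

    ax = axes[0]
    ax.plot(1 - spec, sens, color="tab:blue")
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC (AUC {report.auc:.3f})")

    ax = axes[1]
    cal = report.calibration
    ax.plot(cal["mean_predicted"], cal["fraction_positive"], marker="o", color="tab:orange")
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("mean predicted risk")
    ax.set_ylabel("observed positive fraction")
    ax.set_title("Calibration (10 bins)")

    ax = axes[2]
    hist = report.histogram
    ax.bar(hist["bin_lo"], hist["count"], width=hist["bin_hi"] - hist["bin_lo"], align="edge")
    ax.axvline(report.fixed_tv_point.threshold, color="k", ls=":", label="fixed TV")
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("count")
    ax.set_title("Predictions")
    ax.legend()

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
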