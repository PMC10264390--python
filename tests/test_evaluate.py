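"""Evaluation statistics: AUC, DeLong, operating points, calibration, kappa."""

import numpy as np
import pandas as pd
import pytest

from fundusnorm.evaluate import (
    roc_auc,
    delong_ci,
    delong_interval,
    balanced_operating_point,
    sensitivity_at_specificity,
    fixed_threshold_point,
    aggregate_to_participant,
    calibration_curve,
    cohens_kappa,
    covariate_association,
    compare_score_vs_vcdr,
    evaluate_cohort,
    prediction_histogram,
)


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def brute_force_points(scores, labels):
    """Every achievable operating point by exhaustive threshold scan."""
    pts = []
    for t in list(np.unique(scores)) + [np.max(scores) + 1]:
        calls = scores >= t
        sens = np.mean(calls[labels == 1])
        spec = np.mean(~calls[labels == 0])
        pts.append((float(t), float(sens), float(spec)))
    return pts


def _random_instance(rng, n_max=50):
    n = int(rng.integers(4, n_max + 1))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
    if labels.sum() == 0 or labels.sum() == n:
        labels[0], labels[-1] = 0, 1
    # mix of continuous and heavily tied scores
    if rng.uniform() < 0.5:
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
    else:
        scores = np.round(rng.uniform(size=n), 2)
    return scores.astype(float), labels


def test_auc_separated_and_inverted():
    scores = np.array([0.9, 0.8, 0.1, 0.2])
    labels = np.array([1, 1, 0, 0])
    assert roc_auc(scores, labels) == 1.0
    assert roc_auc(scores, 1 - labels) == 0.0


def test_auc_matches_pairwise_concordance():
    rng = np.random.default_rng(17)
    for _ in range(50):
        scores, labels = _random_instance(rng, n_max=30)
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores, labels = _random_instance(rng)
    a = roc_auc(scores, labels)
    assert roc_auc(np.exp(3 * scores), labels) == pytest.approx(a, abs=1e-12)
    assert roc_auc(scores**3, labels) == pytest.approx(a, abs=1e-12)


def test_auc_complement_identity_tie_free():
    rng = np.random.default_rng(4)
    scores = rng.permutation(np.linspace(0.01, 0.99, 40))
    labels = (rng.uniform(size=40) < 0.4).astype(int)
    labels[:2] = [0, 1]
    assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)


def test_auc_degenerate_labels_raise():
    with pytest.raises(ValueError, match="degenerate"):
        roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


def test_delong_degenerate_interval_flagged():
    scores = np.array([0.9, 0.8, 0.1, 0.2])
    labels = np.array([1, 1, 0, 0])
    with pytest.warns(UserWarning, match="degenerate"):
        res = delong_interval(scores, labels)
    assert res.degenerate and (res.lo, res.hi) == (1.0, 1.0)


def test_delong_agrees_with_bootstrap():
    """DeLong interval overlaps a percentile bootstrap; widths comparable."""
    rng = np.random.default_rng(8)
    n = 200
    labels = (rng.uniform(size=n) < 0.3).astype(int)
    vcdr = np.where(labels == 1, rng.beta(8, 3.5, n), rng.beta(3.5, 8, n))
    scores = np.clip(vcdr + rng.normal(0, 0.15, n), 0, 1)
    lo, hi = delong_ci(scores, labels)
    boots = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        if labels[idx].sum() in (0, n):
            continue
        boots.append(roc_auc(scores[idx], labels[idx]))
    b_lo, b_hi = np.percentile(boots, [2.5, 97.5])
    assert max(lo, b_lo) < min(hi, b_hi)  # intervals overlap
    assert abs((hi - lo) - (b_hi - b_lo)) < 0.3 * (b_hi - b_lo)


def test_delong_duplication_narrows_interval():
    rng = np.random.default_rng(9)
    n = 80
    labels = (rng.uniform(size=n) < 0.4).astype(int)
    labels[:2] = [0, 1]
    scores = np.clip(labels * 0.3 + rng.uniform(size=n) * 0.7, 0, 1)
    lo1, hi1 = delong_ci(scores, labels)
    lo2, hi2 = delong_ci(np.tile(scores, 2), np.tile(labels, 2))
    assert (hi2 - lo2) < (hi1 - lo1)


def test_balanced_point_perfect_separation():
    op = balanced_operating_point(
        np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])
    )
    assert op.sensitivity == op.specificity == 1.0


def test_balanced_point_toy_set_matches_scan():
    scores = np.array([0.9, 0.6, 0.4, 0.5, 0.3, 0.2])
    labels = np.array([1, 1, 1, 0, 0, 0])
    op = balanced_operating_point(scores, labels)
    pts = brute_force_points(scores, labels)
    best = min(pts, key=lambda p: (abs(p[1] - p[2]), -(p[1] + p[2]), p[0]))
    assert (op.threshold, op.sensitivity, op.specificity) == best


def test_balanced_point_all_equal_scores_flagged():
    op = balanced_operating_point(np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 0]))
    assert op.sensitivity + op.specificity == 1.0
    assert op.degenerate


def test_operating_points_match_exhaustive_scan_randomized():
    rng = np.random.default_rng(23)
    for _ in range(200):
        scores, labels = _random_instance(rng)
        pts = brute_force_points(scores, labels)
        op = balanced_operating_point(scores, labels)
        best = min(pts, key=lambda p: (abs(p[1] - p[2]), -(p[1] + p[2]), p[0]))
        assert (op.threshold, op.sensitivity, op.specificity) == pytest.approx(best)
        sas = sensitivity_at_specificity(scores, labels)
        for target, got in sas.items():
            ok = [p for p in pts if p[2] >= target]
            assert got.sensitivity == pytest.approx(max(p[1] for p in ok))


def test_sensitivity_at_specificity_perfect_scorer():
    sas = sensitivity_at_specificity(
        np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])
    )
    assert all(op.sensitivity == 1.0 for op in sas.values())


def test_sensitivity_at_specificity_null_scorer():
    """Random scores: sensitivity at spec target t approaches 1 - t."""
    rng = np.random.default_rng(31)
    n = 20000
    scores = rng.uniform(size=n)
    labels = (rng.uniform(size=n) < 0.5).astype(int)
    sas = sensitivity_at_specificity(scores, labels)
    for target, op in sas.items():
        assert op.sensitivity == pytest.approx(1 - target, abs=0.02)


def test_fixed_threshold_confusion_matrix_arithmetic():
    """TP=45, FN=5, TN=90, FP=10 at the cut gives sens = spec = 0.90."""
    scores = np.concatenate(
        [np.full(45, 0.8), np.full(5, 0.6), np.full(90, 0.6), np.full(10, 0.8)]
    )
    labels = np.concatenate([np.ones(50, int), np.zeros(100, int)])
    op = fixed_threshold_point(scores, labels, tv=0.7)
    assert op.sensitivity == pytest.approx(0.90)
    assert op.specificity == pytest.approx(0.90)
    assert op.sensitivity_ci[0] < 0.90 < op.sensitivity_ci[1]


def test_fixed_threshold_edge_cases():
    scores = np.array([0.71, 0.71, 0.69, 0.69])
    labels = np.array([1, 1, 0, 0])
    op = fixed_threshold_point(scores, labels, tv=0.7)
    assert op.sensitivity == 1.0 and op.specificity == 1.0
    op0 = fixed_threshold_point(scores, labels, tv=0.0)
    assert op0.sensitivity == 1.0 and op0.specificity == 0.0


def test_aggregate_max_of_eyes():
    frame = pd.DataFrame(
        {
            "participant_id": ["a", "a", "b"],
            "score": [0.4, 0.8, 0.6],
            "label": [1, 1, 0],
        }
    )
    out = aggregate_to_participant(frame)
    assert len(out) == 2
    assert out.loc[out["participant_id"] == "a", "score"].item() == 0.8
    assert out.loc[out["participant_id"] == "b", "score"].item() == 0.6


def test_aggregate_invariant_to_eye_order():
    rng = np.random.default_rng(12)
    n = 60
    frame = pd.DataFrame(
        {
            "participant_id": np.repeat([f"p{i}" for i in range(n // 2)], 2),
            "score": rng.uniform(size=n),
            "label": np.repeat((rng.uniform(size=n // 2) < 0.3).astype(int), 2),
        }
    )
    if frame.groupby("participant_id")["label"].max().sum() in (0, n // 2):
        frame.loc[0:1, "label"] = [1, 1]
    a = aggregate_to_participant(frame)
    shuffled = frame.sample(frac=1.0, random_state=1)
    b = aggregate_to_participant(shuffled).sort_values("participant_id").reset_index(drop=True)
    auc_a = roc_auc(a["score"], a["label"])
    auc_b = roc_auc(b["score"], b["label"])
    assert auc_a == pytest.approx(auc_b, abs=1e-12)
    assert len(a) == frame["participant_id"].nunique()


def test_calibration_single_bin():
    scores = np.full(12, 0.05)
    labels = np.zeros(12, int)
    labels[0] = 1  # keep both classes present
    cal = calibration_curve(scores, labels)
    assert len(cal) == 1
    assert cal["count"].iloc[0] == 12


def test_calibration_counts_conserved_and_well_calibrated():
    rng = np.random.default_rng(3)
    n = 100_000
    scores = rng.uniform(size=n)
    labels = (rng.uniform(size=n) < scores).astype(int)
    cal = calibration_curve(scores, labels)
    assert cal["count"].sum() == n
    assert (cal["fraction_positive"] - cal["mean_predicted"]).abs().max() < 0.02


def test_kappa_identical_ratings():
    r = ["no", "suspect", "definite"] * 10
    assert cohens_kappa(r, list(r), positive_classes=("suspect", "definite")) == 1.0


def test_kappa_hand_computed_two_by_two():
    """a=20 both-positive, b=c=5 discordant, d=20: po=0.8, pe=0.5, kappa=0.6."""
    a = ["definite"] * 20 + ["definite"] * 5 + ["no"] * 5 + ["no"] * 20
    b = ["definite"] * 20 + ["no"] * 5 + ["definite"] * 5 + ["no"] * 20
    assert cohens_kappa(a, b) == pytest.approx(0.6)


def test_kappa_constant_rater_flagged():
    with pytest.warns(UserWarning, match="undefined"):
        k = cohens_kappa(["no"] * 10, ["no"] * 10)
    assert np.isnan(k)


def test_covariate_association_exact_and_sign():
    rng = np.random.default_rng(6)
    score = rng.uniform(size=100)
    frame = pd.DataFrame({"score": score, "same": score, "anti": -score + 1})
    out = covariate_association(frame, ["same", "anti"])
    assert out.loc[out["covariate"] == "same", "r"].item() == pytest.approx(1.0)
    assert out.loc[out["covariate"] == "anti", "r"].item() < 0


def test_covariate_association_null_covariate():
    rng = np.random.default_rng(7)
    frame = pd.DataFrame(
        {"score": rng.uniform(size=500), "iop": rng.normal(15, 3, size=500)}
    )
    out = covariate_association(frame, ["iop"])
    assert abs(out["r"].item()) < 0.1
    assert out["n"].item() == 500


def test_covariate_missing_values_dropped_pairwise():
    frame = pd.DataFrame(
        {"score": [0.1, 0.2, 0.3, 0.4], "md": [1.0, np.nan, 3.0, 4.0]}
    )
    out = covariate_association(frame, ["md"])
    assert out["n"].item() == 3


def test_compare_score_vs_vcdr_identity_and_dominance():
    rng = np.random.default_rng(10)
    n = 300
    labels = (rng.uniform(size=n) < 0.3).astype(int)
    vcdr = np.clip(
        np.where(labels == 1, rng.beta(8, 3.5, n), rng.beta(3.5, 8, n)), 0, 1
    )
    frame = pd.DataFrame(
        {"participant_id": [f"p{i}" for i in range(n)], "score": vcdr,
         "label": labels, "vcdr": vcdr}
    )
    cmp_same = compare_score_vs_vcdr(frame)
    assert cmp_same["score"]["auc"] == cmp_same["vcdr"]["auc"]
    # score with extra signal dominates the vcdr baseline
    better = np.clip(vcdr + labels * 0.2, 0, 1)
    frame2 = frame.assign(score=better)
    cmp_dom = compare_score_vs_vcdr(frame2)
    assert cmp_dom["score"]["auc"] >= cmp_dom["vcdr"]["auc"]


def test_compare_requires_vcdr_column():
    frame = pd.DataFrame({"score": [0.1, 0.9], "label": [0, 1]})
    with pytest.raises(ValueError, match="vcdr"):
        compare_score_vs_vcdr(frame)


def test_evaluate_cohort_report_roundtrip(tmp_path):
    rng = np.random.default_rng(14)
    n = 120
    labels = (rng.uniform(size=n) < 0.3).astype(int)
    vcdr = np.clip(
        np.where(labels == 1, rng.beta(8, 3.5, n), rng.beta(3.5, 8, n)), 0, 1
    )
    scores = np.clip(vcdr + rng.normal(0, 0.1, n), 0, 1)
    frame = pd.DataFrame(
        {
            "participant_id": np.repeat([f"p{i}" for i in range(n // 2)], 2),
            "score": scores,
            "label": np.repeat(labels[: n // 2], 2),
            "vcdr": vcdr,
        }
    )
    report = evaluate_cohort(frame, level="participant", compare_vcdr=True)
    assert report.ci95[0] <= report.auc <= report.ci95[1]
    assert report.calibration["count"].sum() == report.n
    assert report.n == n // 2
    text = report.to_json(tmp_path / "report.json")
    assert (tmp_path / "report.json").exists()
    assert "balanced_point" in text
    assert "AUC" in report.summary()


def test_prediction_histogram_conserves_counts():
    scores = np.random.default_rng(1).uniform(size=500)
    hist = prediction_histogram(scores)
    assert hist["count"].sum() == 500
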