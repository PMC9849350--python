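"""Evaluation metrics: worked examples, independent oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (
    average_precision_score,
    matthews_corrcoef,
    roc_auc_score,
)

from capsite.metrics import (
    ConfusionCounts,
    auroc_score,
    average_precision,
    classification_metrics,
    confusion_counts,
    evaluate,
    pr_curve,
)

# -- confusion counts ----------------------------------------------------------


def test_confusion_basic():
    c = confusion_counts([0.9, 0.1], [1, 0], 0.5)
    assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)


def test_confusion_all_below_threshold():
    c = confusion_counts([0.1, 0.2, 0.3], [1, 0, 1], 0.5)
    assert c.TP == 0 and c.FP == 0 and c.FN == 2 and c.TN == 1


def test_confusion_boundary_score_is_positive():
    c = confusion_counts([0.5], [0], 0.5)
    assert c.FP == 1


# -- threshold metrics ---------------------------------------------------------


def test_worked_confusion_table():
    """TP=2, TN=3, FP=1, FN=1 -> MCC = 5/12, F1 = 2/3."""
    out = classification_metrics(ConfusionCounts(TP=2, FP=1, TN=3, FN=1))
    assert out["MCC"] == pytest.approx(5 / 12)
    assert out["F1"] == pytest.approx(2 / 3)
    assert out["TPR"] == pytest.approx(2 / 3)
    assert out["TNR"] == pytest.approx(3 / 4)
    assert out["Pre"] == pytest.approx(2 / 3)
    assert out["ACC"] == pytest.approx(5 / 7)


def test_perfect_predictions():
    out = classification_metrics(ConfusionCounts(TP=4, FP=0, TN=6, FN=0))
    for key in ("TPR", "TNR", "Pre", "ACC", "F1", "MCC"):
        assert out[key] == pytest.approx(1.0)


def test_no_association_balanced_table():
    out = classification_metrics(ConfusionCounts(TP=5, FP=5, TN=5, FN=5))
    assert out["MCC"] == pytest.approx(0.0)


def test_zero_denominator_reported_as_zero(caplog):
    with caplog.at_level("INFO", logger="capsite"):
        out = classification_metrics(ConfusionCounts(TP=0, FP=0, TN=10, FN=0))
    assert out["Pre"] == 0.0 and out["TPR"] == 0.0
    assert "zero denominator" in caplog.text


def test_empty_table_is_error():
    with pytest.raises(ValueError):
        classification_metrics(ConfusionCounts(0, 0, 0, 0))


def test_metric_bounds_random_tables(rng):
    for _ in range(10_000):
        tp, fp, tn, fn = rng.integers(0, 50, size=4)
        if tp + fp + tn + fn == 0:
            continue
        out = classification_metrics(
            ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
        )
        for key in ("TPR", "TNR", "Pre", "ACC", "F1"):
            assert 0.0 <= out[key] <= 1.0
        assert -1.0 <= out["MCC"] <= 1.0


def test_mcc_matches_sklearn(rng):
    y = rng.integers(0, 2, 200)
    calls = rng.integers(0, 2, 200)
    c = confusion_counts(calls.astype(float), y, threshold=0.5)
    ours = classification_metrics(c)["MCC"]
    assert ours == pytest.approx(matthews_corrcoef(y, calls), abs=1e-12)


# -- AUROC ---------------------------------------------------------------------


def brute_force_auroc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_worked_example():
    assert auroc_score([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(0.5)


def test_auroc_perfect_separation():
    assert auroc_score([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0


def test_auroc_all_ties():
    assert auroc_score([0.3] * 6, [1, 0, 1, 0, 0, 1]) == pytest.approx(0.5)


def test_auroc_single_class_error():
    with pytest.raises(ValueError):
        auroc_score([0.1, 0.2], [1, 1])


def test_auroc_matches_brute_force(rng):
    for _ in range(100):
        n = int(rng.integers(4, 30))
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        assert auroc_score(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )


# -- average precision ---------------------------------------------------------


def cumulative_precision_ap(scores, labels):
    """Independent oracle: explicit threshold sweep."""
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        calls = scores >= t
        tp = np.sum(calls & (labels == 1))
        recall = tp / n_pos
        precision = tp / calls.sum()
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def test_ap_worked_example():
    """(0.5-0)*1 + 0*0.5 + (1-0.5)*(2/3) = 5/6."""
    assert average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(5 / 6)


def test_ap_perfect_ranking():
    assert average_precision([0.9, 0.8, 0.2], [1, 1, 0]) == 1.0


def test_ap_random_scores_near_prevalence(rng):
    values = []
    for _ in range(20):
        labels = (rng.random(1000) < 0.10).astype(int)
        values.append(average_precision(rng.random(1000), labels))
    assert abs(np.mean(values) - 0.10) < 0.03


def test_ap_no_positives_error():
    with pytest.raises(ValueError):
        average_precision([0.3, 0.4], [0, 0])


def test_ap_matches_independent_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(4, 40))
        scores = np.round(rng.random(n), 1)
        labels = rng.integers(0, 2, n)
        if labels.sum() == 0:
            continue
        assert average_precision(scores, labels) == pytest.approx(
            cumulative_precision_ap(scores, labels), abs=1e-9
        )


def test_ap_matches_sklearn(rng):
    scores = rng.random(300)
    labels = (rng.random(300) < 0.15).astype(int)
    assert average_precision(scores, labels) == pytest.approx(
        average_precision_score(labels, scores), abs=1e-12
    )


def test_auroc_matches_sklearn(rng):
    scores = rng.random(300)
    labels = (rng.random(300) < 0.15).astype(int)
    assert auroc_score(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12
    )


# -- invariances and the full report ------------------------------------------


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_ranking_metrics_monotone_invariant(seed):
    rng = np.random.default_rng(seed)
    scores = rng.random(50)
    labels = rng.integers(0, 2, 50)
    if labels.min() == labels.max():
        return
    transformed = np.exp(3.0 * scores)  # strictly monotone
    assert auroc_score(scores, labels) == pytest.approx(
        auroc_score(transformed, labels), abs=1e-12
    )
    assert average_precision(scores, labels) == pytest.approx(
        average_precision(transformed, labels), abs=1e-12
    )


def test_evaluate_report_fields(rng):
    scores = rng.random(200)
    labels = (rng.random(200) < 0.2).astype(int)
    report = evaluate(scores, labels)
    d = report.as_dict()
    assert set(d) == {
        "TPR", "TNR", "Pre", "ACC", "F1", "MCC", "AUROC", "AP",
        "threshold", "n_residues",
    }
    assert report.n_residues == 200
    assert "AUROC" in str(report)


def test_evaluate_match_prevalence(rng):
    scores = rng.random(500)
    labels = (rng.random(500) < 0.2).astype(int)
    report = evaluate(scores, labels, match_prevalence=True)
    calls = (scores >= report.threshold).sum()
    assert calls == labels.sum()


def test_pr_curve_rows(rng):
    scores = rng.random(60)
    labels = (rng.random(60) < 0.3).astype(int)
    curve = pr_curve(scores, labels)
    assert curve.shape[1] == 3
    assert np.all(np.diff(curve[:, 1]) >= 0)  # recall non-decreasing
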