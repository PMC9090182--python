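import json
from pathlib import Path

import numpy as np
import pytest

import muscnet as mn
from muscnet.errors import InputError, MuscnetError
from muscnet.models import best_result, predict_from_score

DATA = Path(__file__).parent / "data"


# --- estimator ---------------------------------------------------------------

def test_separable_training_accuracy(rng):
    X = np.vstack([rng.standard_normal((10, 2)) + 4, rng.standard_normal((10, 2)) - 4])
    y = np.array([1] * 10 + [0] * 10)
    est = mn.train_estimator(X, y, [0, 1])
    preds = [predict_from_score(s) for s in est.decision_scores(X)]
    assert np.mean(np.array(preds) == y) == 1.0


def test_label_flip_negates_scores(rng):
    X = rng.standard_normal((20, 5))
    X[:10] += 1.0
    y = np.array([1] * 10 + [0] * 10)
    s1 = mn.train_estimator(X, y, np.arange(5)).decision_scores(X)
    s2 = mn.train_estimator(X, 1 - y, np.arange(5)).decision_scores(X)
    np.testing.assert_allclose(s1, -s2, atol=0.02)  # up to solver tolerance


def test_decision_scores_match_golden_solver_run():
    golden = json.loads((DATA / "svm_decision_scores_golden.json").read_text())
    rng = np.random.default_rng(golden["seed"])
    X = rng.standard_normal(golden["shape"])
    y = np.array([1] * 20 + [0] * 20)
    X[:20, : golden["signal_cols"]] += golden["signal_shift"]
    est = mn.train_estimator(X, y, np.arange(X.shape[1]),
                             regularization=golden["regularization"])
    np.testing.assert_allclose(
        est.decision_scores(X), golden["decision_scores"], atol=1e-8
    )


def test_empty_selection_falls_back_to_majority(rng):
    X = rng.standard_normal((9, 4))
    y = np.array([1] * 5 + [0] * 4)
    est = mn.train_estimator(X, y, [], metric="PCC")
    assert est.fallback_label == 1
    assert np.all(est.decision_scores(X) == 1.0)


# --- fusion ------------------------------------------------------------------

def test_fuse_arithmetic():
    assert mn.fuse(2.0, -1.0, 0.5) == pytest.approx(0.5)
    assert predict_from_score(mn.fuse(2.0, -1.0, 0.5)) == 1
    assert mn.fuse(2.0, -1.0, 0.1) == pytest.approx(-0.7)
    assert predict_from_score(mn.fuse(2.0, -1.0, 0.1)) == 0
    assert predict_from_score(0.0) == 0  # exact tie goes to the control class


def test_fusing_estimator_with_itself_is_identity(small_pcc_features):
    X, y, _ = small_pcc_features
    base = mn.loocv({"PCC": X}, y, mn.FusionSpec(metric_pair=("PCC", "PCC"), alpha=0.5))
    for alpha in (0.1, 0.3, 0.7, 0.9):
        res = mn.loocv({"PCC": X}, y, mn.FusionSpec(metric_pair=("PCC", "PCC"), alpha=alpha))
        np.testing.assert_array_equal(res.per_subject_prediction, base.per_subject_prediction)


# --- metrics -----------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        ((5, 0, 5, 0), (1.0, 1.0, 1.0)),
        ((0, 5, 0, 5), (0.0, 0.0, 0.0)),
        ((63, 5, 63, 6), (126 / 137, 63 / 68, 63 / 69)),
    ],
)
def test_compute_metrics_ratios(counts, expected):
    acc, sn, sp = mn.compute_metrics(*counts)
    assert (acc, sn, sp) == pytest.approx(expected, abs=1e-12)


def test_compute_metrics_undefined_without_both_classes():
    with pytest.raises(MuscnetError):
        mn.compute_metrics(0, 0, 5, 5)


# --- LOOCV -------------------------------------------------------------------

def test_loocv_accounting_and_strong_effect(small_pcc_features):
    X, y, _ = small_pcc_features
    res = mn.loocv({"PCC": X}, y, mn.FusionSpec(metric_pair=("PCC", "PCC")))
    n = len(y)
    assert res.per_subject_prediction.shape == (n,)
    assert res.TP + res.FN == int((y == 1).sum())
    assert res.TN + res.FP == int((y == 0).sum())
    assert res.Acc == pytest.approx(
        (res.Sn * (res.TP + res.FN) + res.Sp * (res.TN + res.FP)) / n
    )
    assert len(res.per_fold_selected) == n
    # the planted effect is overwhelming: perfect separation expected
    assert res.Acc == 1.0


def test_loocv_no_skill_under_label_permutation(small_pcc_features):
    """Permuting the labels destroys any real skill.  At this sample size
    leave-one-out is additionally biased *below* chance on label-free data
    (removing the test subject leaves its class in the training minority),
    so the permuted mean must sit at or below the chance band, far under
    the true-label accuracy."""
    X, y, _ = small_pcc_features
    rng = np.random.default_rng(7)
    accs = []
    for _ in range(20):
        yp = rng.permutation(y)
        accs.append(mn.loocv({"PCC": X}, yp, mn.FusionSpec(metric_pair=("PCC", "PCC"))).Acc)
    true_acc = mn.loocv({"PCC": X}, y, mn.FusionSpec(metric_pair=("PCC", "PCC"))).Acc
    assert float(np.mean(accs)) <= 0.7
    assert float(np.mean(accs)) < true_acc - 0.3


def test_loocv_shuffle_invariance(small_pcc_features):
    X, y, _ = small_pcc_features
    spec = mn.FusionSpec(metric_pair=("PCC", "PCC"))
    base = mn.loocv({"PCC": X}, y, spec)
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(y))
    shuffled = mn.loocv({"PCC": X[perm]}, y[perm], spec)
    np.testing.assert_array_equal(
        shuffled.per_subject_prediction, base.per_subject_prediction[perm]
    )


def test_alpha_grid_shape_and_max_property(small_pcc_features):
    X, y, _ = small_pcc_features
    spec = mn.FusionSpec(metric_pair=("PCC", "PCC"))
    table = mn.alpha_grid({"PCC": X}, y, spec)
    assert len(table) == 9
    assert [r.config.alpha for r in table] == [round(0.1 * i, 1) for i in range(1, 10)]
    # symmetric pair: all rows identical
    accs = {r.Acc for r in table}
    assert len(accs) == 1
    best = best_result(table)
    assert best.Acc >= table[4].Acc  # argmax dominates the alpha=0.5 row


def test_nested_single_candidate_equals_plain_loocv(small_pcc_features):
    X, y, _ = small_pcc_features
    spec = mn.FusionSpec(metric_pair=("PCC", "PCC"), alpha=0.5, threshold=0.05)
    plain = mn.loocv({"PCC": X}, y, spec)
    nested = mn.nested_loocv({"PCC": X}, y, spec, alphas=(0.5,), thresholds=(0.05,))
    np.testing.assert_array_equal(
        nested.per_subject_prediction, plain.per_subject_prediction
    )
    assert nested.inner_choices == [(0.5, 0.05)] * len(y)


def test_nested_inner_never_sees_held_out_subject(small_pcc_features):
    """Leakage audit: no inner-level filter/train call includes the outer
    held-out subject."""
    X, y, _ = small_pcc_features
    spec = mn.FusionSpec(metric_pair=("PCC", "PCC"))
    log: list = []
    mn.nested_loocv({"PCC": X}, y, spec, alphas=(0.3, 0.7), thresholds=(0.05, 0.2),
                    audit_log=log)
    inner = [e for e in log if e["level"] == "inner"]
    assert inner, "audit log recorded no inner-level calls"
    for entry in inner:
        assert entry["outer_fold"] not in entry["subjects"]


def test_loocv_validates_inputs(rng):
    X = rng.standard_normal((6, 4))
    with pytest.raises(InputError):
        mn.loocv({"PCC": X}, np.array([1, 1, 1, 1, 1, 0]),
                 mn.FusionSpec(metric_pair=("PCC", "PCC")))
    with pytest.raises(InputError):
        mn.loocv({"PCC": X}, np.array([1, 1, 1, 0, 0, 0]),
                 mn.FusionSpec(metric_pair=("PCC", "MIC")))
    with pytest.raises(InputError):
        mn.FusionSpec(metric_pair=("PCC", "MIC"), alpha=0.0)
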