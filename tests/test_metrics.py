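"""Metric formulas against hand-derived cases and loop-based oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgkit import (ClassificationReport, ConfusionMatrix, classification_report,
                    compute_fidelity, confusion_matrix)
from ecgkit.metrics import fidelity_table


# ---------------------------------------------------------------------------
# independent loop-based oracles

def fidelity_oracle(y, yp):
    n = len(y)
    mse = sum((a - b) ** 2 for a, b in zip(y, yp)) / n
    mae = sum(abs(a - b) for a, b in zip(y, yp)) / n
    ybar = sum(y) / n
    ss_res = sum((a - b) ** 2 for a, b in zip(y, yp))
    ss_tot = sum((a - ybar) ** 2 for a in y)
    r2 = 1 - ss_res / ss_tot
    ypbar = sum(yp) / n
    num = sum((a - ybar) * (b - ypbar) for a, b in zip(y, yp))
    den = (sum((a - ybar) ** 2 for a in y)
           * sum((b - ypbar) ** 2 for b in yp)) ** 0.5
    return mse, mae, r2, num / den


def report_oracle(y_true, y_pred, labels):
    per = {}
    for lab in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p == lab)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != lab and p == lab)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p != lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per[lab] = (prec, rec, f1)
    acc = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    return per, acc


class TestFidelity:
    def test_identical_vectors(self):
        x = np.sin(np.linspace(0, 5, 40))
        r = compute_fidelity(x, x)
        assert (r.mse, r.mae) == (0.0, 0.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.pearson_r == pytest.approx(1.0)

    def test_constant_offset_hand_case(self):
        r = compute_fidelity([1, 2, 3, 4], [2, 3, 4, 5])
        assert r.mse == pytest.approx(1.0)
        assert r.mae == pytest.approx(1.0)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(0.2)  # 1 - 4/5

    def test_anti_correlated_hand_case(self):
        r = compute_fidelity([1, 2, 3], [3, 2, 1])
        assert r.pearson_r == pytest.approx(-1.0)
        assert r.mse == pytest.approx(8 / 3)
        assert r.mae == pytest.approx(4 / 3)
        assert r.r_squared == pytest.approx(-3.0)  # may be negative

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_fidelity([1, 2, 3], [1, 2])

    def test_constant_original_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_fidelity([2, 2, 2], [1, 2, 3])

    def test_matches_loop_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y = rng.normal(size=n)
            yp = rng.normal(size=n)
            if np.ptp(y) == 0:
                continue
            r = compute_fidelity(y, yp)
            mse, mae, r2, rr = fidelity_oracle(y.tolist(), yp.tolist())
            assert abs(r.mse - mse) < 1e-12
            assert abs(r.mae - mae) < 1e-12
            assert abs(r.r_squared - r2) < 1e-9
            assert abs(r.pearson_r - rr) < 1e-9

    def test_pearson_affine_invariant_mse_not(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        yp = rng.normal(size=50)
        base = compute_fidelity(y, yp)
        scaled = compute_fidelity(y, 2.0 * yp + 3.0)
        assert scaled.pearson_r == pytest.approx(base.pearson_r, abs=1e-12)
        assert scaled.mse != pytest.approx(base.mse)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = ["N"] * 3 + ["V"] * 2 + ["L"]
        cm = confusion_matrix(y, y)
        assert np.trace(cm.counts) == 6
        assert cm.counts.sum() == 6

    def test_direct_count_case(self):
        cm = confusion_matrix(["N", "N", "V"], ["N", "V", "V"])
        i = {lab: k for k, lab in enumerate(cm.labels)}
        assert cm.counts[i["N"], i["N"]] == 1
        assert cm.counts[i["N"], i["V"]] == 1
        assert cm.counts[i["V"], i["V"]] == 1
        assert cm.total == 3

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        y_true = rng.choice(list("NLRAV"), size=100)
        y_pred = rng.choice(list("NLRAV"), size=100)
        perm = rng.permutation(100)
        a = confusion_matrix(y_true, y_pred)
        b = confusion_matrix(y_true[perm], y_pred[perm])
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["N"], ["Q"])

    def test_row_sums_are_class_supports(self):
        rng = np.random.default_rng(3)
        y_true = rng.choice(list("NLRAV"), size=200)
        y_pred = rng.choice(list("NLRAV"), size=200)
        cm = confusion_matrix(y_true, y_pred)
        for i, lab in enumerate(cm.labels):
            assert cm.counts[i].sum() == int(np.sum(y_true == lab))


class TestClassificationReport:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([10, 5, 5, 3, 2]))
        rep = classification_report(cm)
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.precision.values())
        assert rep.macro_f1 == 1.0

    def test_recall_from_confusion_counts(self):
        # a class with 984 correct of 994 true items
        c = np.diag([984, 50, 50, 50, 50])
        c[0, 3] = 6
        c[0, 4] = 4
        rep = classification_report(ConfusionMatrix(c))
        assert rep.recall["N"] == pytest.approx(984 / 994)

    def test_binary_hand_case(self):
        # TP=3, FP=1, FN=1, TN=5 folded into two classes of a 5x5 table
        c = np.zeros((5, 5), dtype=int)
        c[0, 0] = 3   # TP for class N
        c[1, 0] = 1   # FP (true L predicted N)
        c[0, 1] = 1   # FN
        c[1, 1] = 5   # TN bucket
        rep = classification_report(ConfusionMatrix(c))
        assert rep.precision["N"] == pytest.approx(0.75)
        assert rep.recall["N"] == pytest.approx(0.75)
        assert rep.f1["N"] == pytest.approx(0.75)
        assert rep.accuracy == pytest.approx(0.8)

    def test_matches_loop_oracle_on_random_labelings(self):
        rng = np.random.default_rng(4)
        labels = tuple("NLRAV")
        for _ in range(1000):
            n = int(rng.integers(5, 60))
            y_true = rng.choice(labels, size=n)
            y_pred = rng.choice(labels, size=n)
            rep = classification_report(confusion_matrix(y_true, y_pred))
            per, acc = report_oracle(y_true, y_pred, labels)
            assert abs(rep.accuracy - acc) < 1e-12
            for lab in labels:
                assert abs(rep.precision[lab] - per[lab][0]) < 1e-12
                assert abs(rep.recall[lab] - per[lab][1]) < 1e-12
                assert abs(rep.f1[lab] - per[lab][2]) < 1e-12

    def test_matches_sklearn_macro_averages(self):
        from sklearn.metrics import (accuracy_score,
                                     precision_recall_fscore_support)

        rng = np.random.default_rng(5)
        y_true = rng.choice(list("NLRAV"), size=300)
        y_pred = rng.choice(list("NLRAV"), size=300)
        rep = classification_report(confusion_matrix(y_true, y_pred))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list("NLRAV"), average="macro",
            zero_division=0)
        assert rep.macro_precision == pytest.approx(p, abs=1e-12)
        assert rep.macro_recall == pytest.approx(r, abs=1e-12)
        assert rep.macro_f1 == pytest.approx(f, abs=1e-12)
        assert rep.accuracy == pytest.approx(accuracy_score(y_true, y_pred))

    def test_zero_predicted_positives_warns_not_raises(self):
        c = np.zeros((5, 5), dtype=int)
        c[0, 0] = 10  # nothing ever predicted as L/R/A/V
        with pytest.warns(UserWarning, match="no predicted positives"):
            rep = classification_report(ConfusionMatrix(c))
        assert rep.precision["L"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            classification_report(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


@settings(deadline=None, max_examples=50)
@given(st.integers(0, 10_000))
def test_macro_f1_bounded_by_per_class_extremes(seed):
    rng = np.random.default_rng(seed)
    y_true = rng.choice(list("NLRAV"), size=60)
    y_pred = rng.choice(list("NLRAV"), size=60)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = classification_report(confusion_matrix(y_true, y_pred))
    f1s = list(rep.f1.values())
    assert min(f1s) - 1e-12 <= rep.macro_f1 <= max(f1s) + 1e-12


def test_fidelity_table_layout():
    from ecgkit import FidelityReport

    txt = fidelity_table({"noisy": FidelityReport(0.0025, 0.03, 0.97, 0.99)})
    assert "MSE" in txt and "Correlation" in txt and "noisy" in txt
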