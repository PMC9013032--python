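import numpy as np
import pytest
from scipy import stats

from jscore.evaluation import (
    SplitSpec,
    classification_metrics,
    descriptive_comparison,
    evaluate_variant,
    optimal_cutoff,
    pr_curve,
    roc_curve,
    split_train_test,
)

from conftest import make_encounter


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def mann_whitney_auc(scores, labels):
    """Pairwise concordance over all positive-negative pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


def average_precision_stepsum(scores, labels):
    """AP = sum over recall steps of precision, by direct enumeration."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = y.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in np.unique(-s):
        pred = s >= -t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_force_cutoff(scores, labels):
    """Exhaustive scan of every distinct score as threshold; ties to the
    larger threshold."""
    best = None
    for t in np.unique(scores):
        pred = scores >= t
        fpr = (pred & (labels == 0)).sum() / max((labels == 0).sum(), 1)
        tpr = (pred & (labels == 1)).sum() / max((labels == 1).sum(), 1)
        d = np.hypot(fpr, 1 - tpr)
        if best is None or d < best[0] - 1e-15 or (abs(d - best[0]) <= 1e-15 and t > best[1]):
            best = (d, t)
    return best[1]


def random_instance(rng, n_max=50, tie_prone=True):
    n = int(rng.integers(4, n_max))
    labels = rng.integers(0, 2, n)
    while labels.min() == labels.max():
        labels = rng.integers(0, 2, n)
    if tie_prone and rng.random() < 0.5:
        scores = rng.integers(0, 5, n) / 4.0  # heavy ties
    else:
        scores = rng.random(n)
    return scores.astype(float), labels


# ---------------------------------------------------------------------------


class TestSplit:
    def test_exact_three_to_one(self):
        encounters = [make_encounter([], encounter_id=f"E{i}") for i in range(8)]
        train, test = split_train_test(encounters, SplitSpec(seed=1))
        assert len(train) == 6 and len(test) == 2

    def test_deterministic_under_seed(self):
        encounters = [make_encounter([], encounter_id=f"E{i}") for i in range(40)]
        a = split_train_test(encounters, SplitSpec(seed=9))
        b = split_train_test(encounters, SplitSpec(seed=9))
        assert a == b

    def test_partition_law(self):
        encounters = [make_encounter([], encounter_id=f"E{i}") for i in range(41)]
        train, test = split_train_test(encounters, SplitSpec(seed=3))
        ids = lambda xs: {e.encounter_id for e in xs}
        assert ids(train) | ids(test) == ids(encounters)
        assert not ids(train) & ids(test)
        assert abs(len(train) - round(0.75 * 41)) <= 1

    def test_empty_input_fatal(self):
        with pytest.raises(ValueError):
            split_train_test([], SplitSpec())


class TestRocCurve:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        fpr, tpr, thr, auc = roc_curve(scores, labels)
        assert auc == 1.0
        assert (fpr[0], tpr[0]) == (0.0, 0.0) and (fpr[-1], tpr[-1]) == (1.0, 1.0)

    def test_reversed_scores_flip_auc(self):
        rng = np.random.default_rng(2)
        scores, labels = random_instance(rng)
        _, _, _, auc = roc_curve(scores, labels)
        _, _, _, auc_rev = roc_curve(-scores, labels)
        assert abs(auc + auc_rev - 1.0) < 1e-12

    def test_auc_equals_mann_whitney_concordance(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            scores, labels = random_instance(rng)
            _, _, _, auc = roc_curve(scores, labels)
            assert abs(auc - mann_whitney_auc(scores, labels)) < 1e-12

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="class"):
            roc_curve(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_curve_monotone_nondecreasing(self):
        rng = np.random.default_rng(8)
        scores, labels = random_instance(rng)
        fpr, tpr, _, _ = roc_curve(scores, labels)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


class TestPrCurve:
    def test_perfect_classifier(self):
        _, _, _, ap = pr_curve(np.array([0.9, 0.8, 0.2]), np.array([1, 1, 0]))
        assert ap == 1.0

    def test_all_positive_labels_degenerate(self):
        precision, recall, _, ap = pr_curve(
            np.array([0.9, 0.5, 0.1]), np.array([1, 1, 1])
        )
        assert ap == 1.0
        assert np.allclose(precision, 1.0)

    def test_matches_step_sum_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            scores, labels = random_instance(rng)
            if labels.sum() == 0:
                continue
            _, _, _, ap = pr_curve(scores, labels)
            assert abs(ap - average_precision_stepsum(scores, labels)) < 1e-10

    def test_zero_positives_fatal(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve(np.array([0.4, 0.2]), np.array([0, 0]))


class TestOptimalCutoff:
    def test_perfect_classifier_zero_distance(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        cut = optimal_cutoff(scores, labels)
        m = classification_metrics(scores, labels, cut)
        assert m["fpr"] == 0.0 and m["fnr"] == 0.0

    def test_equals_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            scores, labels = random_instance(rng, n_max=100)
            assert optimal_cutoff(scores, labels) == brute_force_cutoff(scores, labels)

    def test_single_threshold_returned(self):
        scores = np.array([0.4, 0.4, 0.4, 0.4])
        labels = np.array([1, 0, 1, 0])
        assert optimal_cutoff(scores, labels) == 0.4


class TestClassificationMetrics:
    def test_separable_case(self):
        m = classification_metrics(
            np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]), 0.5
        )
        assert m["accuracy"] == 1.0 and m["fpr"] == 0.0 and m["fnr"] == 0.0

    def test_cutoff_above_max_predicts_all_low(self):
        m = classification_metrics(
            np.array([0.9, 0.8, 0.2]), np.array([1, 0, 1]), 0.95
        )
        assert m["fnr"] == 1.0 and m["fpr"] == 0.0

    def test_matches_confusion_counting(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            scores, labels = random_instance(rng)
            cutoff = float(rng.random())
            m = classification_metrics(scores, labels, cutoff)
            tp = fp = tn = fn = 0
            for s, y in zip(scores, labels):
                if s >= cutoff and y == 1:
                    tp += 1
                elif s >= cutoff and y == 0:
                    fp += 1
                elif s < cutoff and y == 1:
                    fn += 1
                else:
                    tn += 1
            assert m["accuracy"] == (tp + tn) / len(labels)
            assert m["accuracy"] == pytest.approx(1 - (fp + fn) / len(labels))
            if fp + tn:
                assert m["fpr"] == fp / (fp + tn)
            if fn + tp:
                assert m["fnr"] == fn / (fn + tp)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(23)
        scores, labels = random_instance(rng, n_max=80)
        cuts = np.sort(rng.random(10))
        ms = [classification_metrics(scores, labels, c) for c in cuts]
        for lo, hi in zip(ms, ms[1:]):
            assert hi["fpr"] <= lo["fpr"] + 1e-12
            assert hi["fnr"] >= lo["fnr"] - 1e-12


class TestDescriptiveComparison:
    def test_identical_cohorts_pvalues_near_one(self):
        encounters = [
            make_encounter([], encounter_id=f"E{i}", age=30 + i % 40,
                           sex="F" if i % 2 else "M", admit_soi=1 + i % 4,
                           discharge_soi=1 + (i + 1) % 4)
            for i in range(40)
        ]
        rep = descriptive_comparison(encounters, list(encounters))
        assert rep["age"]["p_value"] > 0.99
        for var in ("sex", "race", "admit_soi", "discharge_soi"):
            assert rep[var]["p_value"] > 0.99
            np.testing.assert_allclose(sum(rep[var]["train_proportions"]), 1.0)
            assert rep[var]["train_proportions"] == rep[var]["test_proportions"]

    def test_chi_square_matches_hand_computation(self):
        # 2x2 table: train sexes 10 M / 20 F, test 20 M / 10 F.
        # All expected cells are 15; Pearson X^2 = 4 * (5^2/15) = 20/3.
        train = [
            make_encounter([], encounter_id=f"T{i}", sex="M" if i < 10 else "F")
            for i in range(30)
        ]
        test = [
            make_encounter([], encounter_id=f"S{i}", sex="M" if i < 20 else "F")
            for i in range(30)
        ]
        rep = descriptive_comparison(train, test)
        expected_p = stats.chi2.sf(20 / 3, df=1)
        np.testing.assert_allclose(rep["sex"]["p_value"], expected_p, rtol=1e-10)

    def test_empty_cohort_fatal(self):
        with pytest.raises(ValueError):
            descriptive_comparison([], [make_encounter([])])


class TestEvaluateVariant:
    def test_train_equals_test_consistency(self, small_cohort):
        maps, encounters, _ = small_cohort
        sub = encounters[:800]
        report, _ = evaluate_variant(sub, sub, maps, "body_system", "discharge")
        assert report.accuracy == report.train_accuracy
        assert report.n_train == report.n_test == 800

    def test_report_identities_and_order_invariance(self, small_cohort):
        maps, encounters, _ = small_cohort
        train, test = encounters[:1200], encounters[1200:1600]
        rep1, _ = evaluate_variant(train, test, maps, "body_system", "discharge")
        rng = np.random.default_rng(4)
        shuffled = [test[i] for i in rng.permutation(len(test))]
        rep2, _ = evaluate_variant(train, shuffled, maps, "body_system", "discharge")
        assert rep1.accuracy == rep2.accuracy
        assert rep1.fpr == rep2.fpr and rep1.fnr == rep2.fnr
        assert rep1.optimal_cutoff == rep2.optimal_cutoff
        assert 0 <= rep1.roc_auc <= 1 and 0 <= rep1.pr_auc <= 1

    def test_report_serializes(self, small_cohort, tmp_path):
        maps, encounters, _ = small_cohort
        report, _ = evaluate_variant(
            encounters[:900], encounters[900:1200], maps, "comorbidity", "admission"
        )
        import json

        doc = json.loads(report.save(tmp_path / "eval.json").read_text())
        for key in ("roc_auc", "pr_auc", "optimal_cutoff", "accuracy", "fpr", "fnr",
                    "n_train", "n_test", "variant", "phase"):
            assert key in doc
        assert doc["n_predictors"] == 30
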