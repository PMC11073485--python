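import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifscreen import screening as scr
from ifscreen.features import SubjectFeatures, age_group
from ifscreen.screening import (
    CartConstraints,
    ConfusionMatrix,
    DecisionTree,
    classify_fixed_tree_A,
    classify_fixed_tree_B,
    confusion_from_predictions,
    load_fixed_tree,
    loocv,
    metrics,
    predict,
    roc_auc,
    train_cart,
)

from oracles import pairwise_rank_auc


def make_subject(i, label, **features):
    defaults = dict(omega1_bpm=95.0, phi1=-0.3, HR=85.0, omegai1=1.1,
                    omega2_bpm=60.0, phi2=0.4, Rs=1.0, Rd=0.8, age=8.0)
    defaults.update(features)
    return SubjectFeatures(
        subject_id=f"P{i:03d}", lvef=40.0 if label else 60.0, label=bool(label),
        n_cycles=3, age_group=age_group(defaults["age"]), **defaults,
    )


# ---------------------------------------------------------------------------
# fixed published rules
# ---------------------------------------------------------------------------

def rule_A_truth(w1, age, phi1):
    """Independent truth table of the published (omega1, age, phi1) rule."""
    if w1 < 107.6:
        return False
    if age >= 6:
        return True
    return phi1 < -0.65


def rule_B_truth(w1, wi1):
    """Independent truth table of the published (omega1, omegai1) rule."""
    if wi1 > 1.6:
        return True
    if wi1 < 1.22:
        return False
    return w1 > 107.6


class TestFixedTreeA:
    @pytest.mark.parametrize(
        "w1, age, phi1, expected",
        [
            (100, 10, -1.0, False),   # low omega1 is normal regardless of age/phase
            (120, 12, 0.0, True),     # high omega1, school age
            (120, 4, -0.8, True),     # under 6: low phase confirms
            (120, 4, 0.0, False),     # under 6: preserved phase is normal
        ],
    )
    def test_published_examples(self, w1, age, phi1, expected):
        label, path = classify_fixed_tree_A(w1, age, phi1)
        assert label is expected
        assert path[-1] == ("low" if expected else "normal")

    def test_grid_agrees_with_truth_table(self):
        w1s = np.concatenate([np.linspace(60, 160, 21), [107.59, 107.6, 107.61]])
        ages = np.concatenate([np.linspace(0, 20, 11), [5.99, 6.0, 6.01]])
        phis = np.concatenate([np.linspace(-1.5, 0.5, 9), [-0.651, -0.65, -0.649]])
        for w1, age, phi1 in itertools.product(w1s, ages, phis):
            assert classify_fixed_tree_A(w1, age, phi1)[0] == rule_A_truth(w1, age, phi1)

    def test_json_fixture_matches_function(self):
        tree = load_fixed_tree("A")
        rng = np.random.default_rng(2)
        for _ in range(500):
            w1 = float(rng.uniform(60, 160))
            age = float(rng.uniform(0, 20))
            phi1 = float(rng.uniform(-1.5, 0.5))
            label, _ = tree.decide({"omega1_bpm": w1, "age": age, "phi1": phi1})
            assert label == classify_fixed_tree_A(w1, age, phi1)[0]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_fixed_tree_A(float("nan"), 5, -0.3)


class TestFixedTreeB:
    @pytest.mark.parametrize(
        "w1, wi1, expected",
        [
            (90, 1.7, True),     # high normalised index alone
            (150, 1.1, False),   # low normalised index alone
            (110, 1.3, True),    # middle band decided by omega1
            (100, 1.3, False),
        ],
    )
    def test_published_examples(self, w1, wi1, expected):
        label, path = classify_fixed_tree_B(w1, wi1)
        assert label is expected

    def test_grid_agrees_with_truth_table(self):
        w1s = np.concatenate([np.linspace(60, 160, 51), [107.59, 107.6, 107.61]])
        wi1s = np.concatenate([np.linspace(0.5, 2.5, 41), [1.219, 1.22, 1.221, 1.599, 1.6, 1.601]])
        for w1, wi1 in itertools.product(w1s, wi1s):
            assert classify_fixed_tree_B(w1, wi1)[0] == rule_B_truth(w1, wi1)

    def test_json_fixture_matches_function(self):
        tree = load_fixed_tree("B")
        rng = np.random.default_rng(3)
        for _ in range(500):
            w1 = float(rng.uniform(60, 160))
            wi1 = float(rng.uniform(0.5, 2.5))
            label, _ = tree.decide({"omega1_bpm": w1, "omegai1": wi1})
            assert label == classify_fixed_tree_B(w1, wi1)[0]


# ---------------------------------------------------------------------------
# CART training
# ---------------------------------------------------------------------------

class TestTrainCart:
    def test_separable_single_predictor(self):
        rng = np.random.default_rng(0)
        subjects = [make_subject(i, False, omega1_bpm=float(rng.uniform(85, 100)))
                    for i in range(20)]
        subjects += [make_subject(20 + i, True, omega1_bpm=float(rng.uniform(115, 130)))
                     for i in range(20)]
        tree = train_cart(subjects, ["omega1_bpm"])
        assert tree.n_splits == 1
        assert 100.0 < tree.root.threshold < 115.0
        assert all(predict(tree, s)[0] == s.label for s in subjects)

    def test_ten_subjects_cannot_split(self):
        subjects = [make_subject(i, i % 2, omega1_bpm=90.0 + 30 * (i % 2)) for i in range(10)]
        tree = train_cart(subjects, ["omega1_bpm"])
        assert tree.n_splits == 0

    def test_eleven_subjects_can_split(self):
        subjects = [make_subject(i, i % 2 == 0, omega1_bpm=90.0 + 30 * (i % 2 == 0)) for i in range(11)]
        tree = train_cart(subjects, ["omega1_bpm"])
        assert tree.n_splits == 1

    def test_split_budget_honored(self):
        rng = np.random.default_rng(5)
        subjects = [make_subject(i, bool(rng.integers(2)),
                                 omega1_bpm=float(rng.uniform(80, 130)),
                                 omegai1=float(rng.uniform(0.8, 1.8)))
                    for i in range(200)]
        tree = train_cart(subjects, ["omega1_bpm", "omegai1"])
        assert tree.n_splits <= 3
        assert all(n >= 11 for n in tree.split_node_sizes())

    def test_planted_two_threshold_recovery(self):
        # nested structure: omega1 < 105 is all normal; above it, low LVEF
        # iff omegai1 > 1.4 — the greedy optimum is the planted pair
        rng = np.random.default_rng(8)
        subjects = []
        i = 0
        quadrants = [
            (False, (80, 95), (0.9, 1.3), 10),   # low/low
            (False, (80, 95), (1.5, 1.8), 14),   # low omega1, high omegai1
            (False, (115, 130), (0.9, 1.3), 6),  # high omega1, low omegai1
            (True, (115, 130), (1.5, 1.8), 25),  # the planted corner
        ]
        for label, w1r, wir, count in quadrants:
            for _ in range(count):
                subjects.append(make_subject(
                    i, label, omega1_bpm=float(rng.uniform(*w1r)),
                    omegai1=float(rng.uniform(*wir))))
                i += 1
        tree = train_cart(subjects, ["omega1_bpm", "omegai1"])
        assert tree.n_splits <= 3
        assert all(predict(tree, s)[0] == s.label for s in subjects)
        thresholds = {}

        def walk(node):
            if isinstance(node, scr.TreeNode):
                thresholds.setdefault(node.feature, []).append(node.threshold)
                walk(node.left); walk(node.right)
        walk(tree.root)
        # thresholds fall inside the planted midpoint gaps
        assert any(95 <= t <= 115 for t in thresholds.get("omega1_bpm", []))
        assert any(1.3 <= t <= 1.5 for t in thresholds.get("omegai1", []))

    def test_matches_sklearn_reference(self):
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(11)
        subjects = [make_subject(i, bool(rng.integers(2)),
                                 omega1_bpm=float(rng.uniform(80, 130)),
                                 omegai1=float(rng.uniform(0.8, 1.8)))
                    for i in range(120)]
        predictors = ["omega1_bpm", "omegai1"]
        tree = train_cart(subjects, predictors)
        X = np.array([[s.feature(f) for f in predictors] for s in subjects])
        y = np.array([s.label for s in subjects])
        ref = DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=1 + len(predictors) + 1,
            min_samples_split=11, random_state=0,
        ).fit(X, y)
        ours = np.array([predict(tree, s)[0] for s in subjects])
        agreement = float(np.mean(ours == ref.predict(X)))
        assert agreement >= 0.95

    def test_single_class_single_leaf(self):
        subjects = [make_subject(i, False) for i in range(30)]
        tree = train_cart(subjects, ["omega1_bpm"])
        assert tree.n_splits == 0
        label, score = predict(tree, subjects[0])
        assert label is False and score == 0.0


class TestPredict:
    def test_single_leaf_scores_constant(self):
        tree = DecisionTree(root=scr.TreeLeaf(label=False, pos_fraction=0.3, n=10))
        for s in [make_subject(0, False), make_subject(1, True, omega1_bpm=200)]:
            label, score = predict(tree, s)
            assert label is False and score == 0.3

    def test_same_leaf_same_score(self):
        rng = np.random.default_rng(1)
        subjects = [make_subject(i, i >= 15, omega1_bpm=90.0 + 30 * (i >= 15) + float(rng.uniform(0, 5)))
                    for i in range(30)]
        tree = train_cart(subjects, ["omega1_bpm"])
        s1 = make_subject(100, False, omega1_bpm=85.0)
        s2 = make_subject(101, False, omega1_bpm=88.0)
        assert predict(tree, s1) == predict(tree, s2)

    def test_missing_feature_raises(self):
        tree = DecisionTree(root=scr.TreeNode("bogus", 1.0,
                                              scr.TreeLeaf(False, 0.0, 1),
                                              scr.TreeLeaf(True, 1.0, 1)))
        with pytest.raises(KeyError):
            predict(tree, make_subject(0, False))


def test_tree_json_round_trip():
    rng = np.random.default_rng(4)
    subjects = [make_subject(i, bool(rng.integers(2)),
                             omega1_bpm=float(rng.uniform(80, 130))) for i in range(40)]
    tree = train_cart(subjects, ["omega1_bpm"])
    back = DecisionTree.from_json(tree.to_json())
    for s in subjects:
        assert predict(tree, s) == predict(back, s)


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

class TestLoocv:
    def test_model_count(self):
        rng = np.random.default_rng(6)
        subjects = [make_subject(i, i % 3 == 0, omega1_bpm=float(rng.uniform(80, 130)))
                    for i in range(12)]
        pairs = loocv(subjects, ["omega1_bpm"])
        assert len(pairs) == 12
        assert [p[0] for p in pairs] == [s.subject_id for s in subjects]

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        subjects = [make_subject(i, bool(rng.integers(2)),
                                 omega1_bpm=float(rng.uniform(80, 130)),
                                 omegai1=float(rng.uniform(0.8, 1.8)))
                    for i in range(25)]
        base = dict((p[0], p[1:]) for p in loocv(subjects, ["omega1_bpm", "omegai1"]))
        shuffled = subjects[::-1]
        again = dict((p[0], p[1:]) for p in loocv(shuffled, ["omega1_bpm", "omegai1"]))
        assert base == again

    def test_separable_cohort_perfect_heldout(self):
        rng = np.random.default_rng(12)
        subjects = [make_subject(i, False, omega1_bpm=float(rng.uniform(80, 95)))
                    for i in range(20)]
        subjects += [make_subject(20 + i, True, omega1_bpm=float(rng.uniform(120, 135)))
                     for i in range(20)]
        pairs = loocv(subjects, ["omega1_bpm"])
        assert all(pred == truth for _, _, pred, truth in pairs)
        tree = train_cart(subjects, ["omega1_bpm"])
        assert all(predict(tree, s)[0] == s.label for s in subjects)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            loocv([make_subject(0, False), make_subject(1, True)], ["omega1_bpm"])


# ---------------------------------------------------------------------------
# metrics / ROC
# ---------------------------------------------------------------------------

class TestMetrics:
    def test_printed_formulas(self):
        sens, spec, acc = metrics(ConfusionMatrix(TP=5, FP=5, TN=0, FN=0))
        assert sens == 1.0 and spec == 0.0 and acc == 0.5

    def test_undefined_marker(self):
        sens, spec, acc = metrics(ConfusionMatrix(TP=0, FP=2, TN=3, FN=0))
        assert sens is None and spec == 0.6 and acc == 0.6

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_matches_counting_oracle(self, tp, fp, tn, fn):
        cm = ConfusionMatrix(TP=tp, FP=fp, TN=tn, FN=fn)
        sens, spec, acc = metrics(cm)
        # brute-force counting over an explicit labeled prediction list
        preds = [(True, True)] * tp + [(True, False)] * fp + \
                [(False, False)] * tn + [(False, True)] * fn
        pos = [t for _, t in preds if t]
        neg = [t for _, t in preds if not t]
        if pos:
            assert sens == pytest.approx(sum(1 for p, t in preds if p and t) / len(pos))
        else:
            assert sens is None
        if neg:
            assert spec == pytest.approx(sum(1 for p, t in preds if not p and not t) / len(neg))
        else:
            assert spec is None
        if preds:
            assert acc == pytest.approx(sum(1 for p, t in preds if p == t) / len(preds))

    def test_confusion_from_predictions_counts(self):
        pairs = [("a", 0.9, True, True), ("b", 0.8, True, False),
                 ("c", 0.2, False, False), ("d", 0.1, False, True)]
        cm = confusion_from_predictions(pairs)
        assert (cm.TP, cm.FP, cm.TN, cm.FN) == (1, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        points, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0
        assert points[0][:2] == (0.0, 0.0) and points[-1][:2] == (1.0, 1.0)

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 10, [True] * 4 + [False] * 6)
        assert auc == 0.5

    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.normal(size=n), 1)  # coarse => frequent ties
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pairwise_rank_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 60).astype(bool)
        labels[0], labels[1] = True, False
        scores = rng.normal(size=60) + labels
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_curve(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 50).astype(bool)
        labels[:2] = [True, False]
        scores = rng.normal(size=50)
        points, _ = roc_auc(scores, labels)
        fprs = [p[0] for p in points]
        tprs = [p[1] for p in points]
        assert all(x2 >= x1 for x1, x2 in zip(fprs, fprs[1:]))
        assert all(y2 >= y1 for y1, y2 in zip(tprs, tprs[1:]))

    def test_monotone_score_transform_invariance(self):
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 2, 40).astype(bool)
        labels[:2] = [True, False]
        scores = rng.normal(size=40)
        _, auc1 = roc_auc(scores, labels)
        _, auc2 = roc_auc(np.exp(2 * scores), labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [True, True])
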