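"""Low-LVEF screening: fixed decision rules, constrained CART, LOOCV, ROC.

Two families of classifiers are provided.

*Fixed published rules.*  :func:`classify_fixed_tree_A` combines the
systolic intrinsic frequency ``omega1`` (bpm), age (years) and the
systolic phase ``phi1`` (rad) with thresholds 107.6 bpm, 6 years and
-0.65 rad; :func:`classify_fixed_tree_B` combines ``omega1`` and the
HR-normalised index ``omegai1`` with thresholds 1.6, 1.22 and 107.6 bpm.
Published inequalities are strict, so equality at a threshold falls to
the non-strict side (a measure-zero set, encoded for reproducibility).

*Trained trees.*  :func:`train_cart` grows a binary Gini-impurity CART
best-first under two structural constraints: the total number of splits
may not exceed ``1 +`` the number of predictors, and a node may only be
split when it holds more than 10 training samples.  Split thresholds sit
at midpoints between consecutive sorted distinct values; ties in
impurity gain break deterministically (lowest feature index, then
smallest threshold).

Evaluation is leave-one-out cross-validation with deterministic
partitions, pooled into one confusion matrix and one ROC; the AUC is
trapezoidal and coincides with the Mann-Whitney rank statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import SubjectFeatures

__all__ = [
    "OMEGA1_THRESHOLD_BPM",
    "AGE_THRESHOLD_YEARS",
    "PHI1_THRESHOLD",
    "OMEGAI1_HIGH",
    "OMEGAI1_LOW",
    "TreeNode",
    "TreeLeaf",
    "DecisionTree",
    "CartConstraints",
    "ConfusionMatrix",
    "ScreeningReport",
    "classify_fixed_tree_A",
    "classify_fixed_tree_B",
    "load_fixed_tree",
    "train_cart",
    "predict",
    "loocv",
    "metrics",
    "roc_auc",
    "confusion_from_predictions",
    "evaluate_loocv",
]

# Published decision boundaries.
OMEGA1_THRESHOLD_BPM = 107.6   # bpm, top-level systolic IF split
AGE_THRESHOLD_YEARS = 6.0      # years
PHI1_THRESHOLD = -0.65         # rad
OMEGAI1_HIGH = 1.6             # omegai1 above -> low LVEF
OMEGAI1_LOW = 1.22             # omegai1 below -> normal LVEF


# ---------------------------------------------------------------------------
# Fixed published rules
# ---------------------------------------------------------------------------

def classify_fixed_tree_A(omega1_bpm: float, age: float, phi1: float) -> tuple[bool, list[str]]:
    """Published rule on (omega1, age, phi1).

    ``omega1 < 107.6`` is normal regardless of age and phase; above it,
    age >= 6 years confirms low LVEF, while children younger than 6 are
    positive only when ``phi1 < -0.65``.  Returns (label, rule path);
    label True means low LVEF.
    """
    if not all(np.isfinite([omega1_bpm, age, phi1])):
        raise ValueError("inputs must be finite")
    if omega1_bpm < OMEGA1_THRESHOLD_BPM:
        return False, [f"omega1={omega1_bpm:g} < {OMEGA1_THRESHOLD_BPM}", "normal"]
    path = [f"omega1={omega1_bpm:g} >= {OMEGA1_THRESHOLD_BPM}"]
    if age >= AGE_THRESHOLD_YEARS:
        return True, path + [f"age={age:g} >= {AGE_THRESHOLD_YEARS:g}", "low"]
    path.append(f"age={age:g} < {AGE_THRESHOLD_YEARS:g}")
    if phi1 < PHI1_THRESHOLD:
        return True, path + [f"phi1={phi1:g} < {PHI1_THRESHOLD}", "low"]
    return False, path + [f"phi1={phi1:g} >= {PHI1_THRESHOLD}", "normal"]


def classify_fixed_tree_B(omega1_bpm: float, omegai1: float) -> tuple[bool, list[str]]:
    """Published rule on (omega1, omegai1), age-universal.

    ``omegai1 > 1.6`` is low LVEF and ``omegai1 < 1.22`` normal; the
    intermediate band is decided by ``omega1 > 107.6`` bpm.
    """
    if not all(np.isfinite([omega1_bpm, omegai1])):
        raise ValueError("inputs must be finite")
    if omegai1 > OMEGAI1_HIGH:
        return True, [f"omegai1={omegai1:g} > {OMEGAI1_HIGH}", "low"]
    if omegai1 < OMEGAI1_LOW:
        return False, [f"omegai1={omegai1:g} < {OMEGAI1_LOW}", "normal"]
    path = [f"{OMEGAI1_LOW} <= omegai1={omegai1:g} <= {OMEGAI1_HIGH}"]
    if omega1_bpm > OMEGA1_THRESHOLD_BPM:
        return True, path + [f"omega1={omega1_bpm:g} > {OMEGA1_THRESHOLD_BPM}", "low"]
    return False, path + [f"omega1={omega1_bpm:g} <= {OMEGA1_THRESHOLD_BPM}", "normal"]


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeLeaf:
    """Terminal node: majority label, positive-class fraction and size."""

    label: bool
    pos_fraction: float
    n: int


@dataclass
class TreeNode:
    """Internal node: route left when ``feature < threshold``, else right.

    ``strict_right`` flips the boundary so equality routes left (used to
    encode published strict '>' rules exactly)."""

    feature: str
    threshold: float
    left: "TreeNode | TreeLeaf"
    right: "TreeNode | TreeLeaf"
    strict_right: bool = False


@dataclass
class DecisionTree:
    """A binary classification tree over named subject features."""

    root: TreeNode | TreeLeaf
    predictors: tuple[str, ...] = ()
    schema_version: int = 1

    @property
    def n_splits(self) -> int:
        def count(node) -> int:
            if isinstance(node, TreeLeaf):
                return 0
            return 1 + count(node.left) + count(node.right)
        return count(self.root)

    def split_node_sizes(self) -> list[int]:
        sizes: list[int] = []

        def walk(node, n_hint=None):
            if isinstance(node, TreeNode):
                if getattr(node, "n", None) is not None:
                    sizes.append(node.n)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return sizes

    def decide(self, features: Mapping[str, float] | SubjectFeatures) -> tuple[bool, float]:
        getter = features.feature if isinstance(features, SubjectFeatures) else (
            lambda name: float(features[name])
        )
        node = self.root
        while isinstance(node, TreeNode):
            x = getter(node.feature)
            goes_right = x > node.threshold if node.strict_right else x >= node.threshold
            node = node.right if goes_right else node.left
        return node.label, node.pos_fraction

    # -- JSON serialization (schema: {"schema_version", "predictors", "root"})
    def to_json(self) -> str:
        def enc(node):
            if isinstance(node, TreeLeaf):
                return {"leaf": True, "label": bool(node.label),
                        "pos_fraction": node.pos_fraction, "n": node.n}
            d = {"leaf": False, "feature": node.feature, "threshold": node.threshold,
                 "strict_right": node.strict_right,
                 "left": enc(node.left), "right": enc(node.right)}
            if getattr(node, "n", None) is not None:
                d["n"] = node.n
            return d
        return json.dumps(
            {"schema_version": self.schema_version,
             "predictors": list(self.predictors), "root": enc(self.root)},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        obj = json.loads(text)

        def dec(d):
            if d["leaf"]:
                return TreeLeaf(bool(d["label"]), float(d["pos_fraction"]), int(d["n"]))
            node = TreeNode(d["feature"], float(d["threshold"]),
                            dec(d["left"]), dec(d["right"]),
                            strict_right=bool(d.get("strict_right", False)))
            if "n" in d:
                node.n = int(d["n"])
            return node

        return cls(root=dec(obj["root"]), predictors=tuple(obj.get("predictors", ())),
                   schema_version=int(obj.get("schema_version", 1)))


_TREE_DIR = Path(__file__).parent / "trees"


def load_fixed_tree(which: str) -> DecisionTree:
    """Load one of the published trees shipped as JSON fixtures ('A' or 'B')."""
    name = {"A": "fixed_tree_a.json", "B": "fixed_tree_b.json"}[which.upper()]
    return DecisionTree.from_json((_TREE_DIR / name).read_text())


# ---------------------------------------------------------------------------
# CART training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CartConstraints:
    """Structural constraints of the trained trees.

    ``max_splits`` defaults to ``1 + #predictors``; ``min_split_size`` is
    the smallest node size eligible for splitting — 'greater than 10'
    samples, i.e. at least 11.
    """

    max_splits: int | None = None
    min_split_size: int = 11

    def resolved_max_splits(self, n_predictors: int) -> int:
        return self.max_splits if self.max_splits is not None else 1 + n_predictors


def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = y.mean()
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray):
    """Best (feature, threshold, impurity decrease) for one node, or None.

    Thresholds at midpoints of consecutive sorted distinct values; the
    decrease is the node's weighted Gini improvement.  Deterministic
    tie-break: lowest feature index, then smallest threshold.
    """
    n = y.size
    base = _gini(y) * n
    best = None
    for j in range(X.shape[1]):
        xs = X[:, j]
        order = np.argsort(xs, kind="stable")
        xs_s, y_s = xs[order], y[order]
        distinct = np.flatnonzero(np.diff(xs_s) > 0)
        if distinct.size == 0:
            continue
        pos_cum = np.cumsum(y_s)
        for k in distinct:
            nl = k + 1
            nr = n - nl
            pl = pos_cum[k] / nl
            pr = (pos_cum[-1] - pos_cum[k]) / nr
            child = 2.0 * pl * (1 - pl) * nl + 2.0 * pr * (1 - pr) * nr
            gain = base - child
            thr = 0.5 * (xs_s[k] + xs_s[k + 1])
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12 or
                                 (abs(gain - best[2]) <= 1e-12 and (j, thr) < (best[0], best[1]))):
                best = (j, thr, gain)
    return best


class _GrowingNode:
    __slots__ = ("idx", "leaf", "order")

    def __init__(self, idx: np.ndarray, order: int):
        self.idx = idx
        self.leaf: TreeLeaf | TreeNode | None = None
        self.order = order


def train_cart(
    table: Sequence[SubjectFeatures],
    predictors: Sequence[str],
    constraints: CartConstraints | None = None,
) -> DecisionTree:
    """Grow a constrained Gini CART on the given predictors.

    Growth is best-first: among all currently splittable leaves the split
    with the largest impurity decrease is applied, until the split budget
    ``max_splits`` is spent or no admissible split improves impurity.
    Single-class input yields a single-leaf tree.
    """
    if len(table) < 1:
        raise ValueError("training table is empty")
    constraints = constraints or CartConstraints()
    X = np.array([[s.feature(f) for f in predictors] for s in table], dtype=float)
    y = np.array([bool(s.label) for s in table])
    max_splits = constraints.resolved_max_splits(len(predictors))

    def make_leaf(idx: np.ndarray) -> TreeLeaf:
        frac = float(y[idx].mean()) if idx.size else 0.0
        return TreeLeaf(label=frac > 0.5, pos_fraction=frac, n=int(idx.size))

    # frontier of splittable leaves with their best candidate split
    all_idx = np.arange(len(table))
    parent_link: dict[int, tuple] = {}
    root_holder: list = [make_leaf(all_idx)]

    frontier: list[tuple] = []  # (gain, feature_idx, threshold, order, idx, attach)

    counter = [0]

    def consider(idx: np.ndarray, attach):
        if idx.size < constraints.min_split_size:
            return
        if np.unique(y[idx]).size < 2:
            return
        found = _best_split(X[idx], y[idx])
        if found is not None:
            j, thr, gain = found
            counter[0] += 1
            frontier.append((gain, j, thr, counter[0], idx, attach))

    def attach_root(node):
        root_holder[0] = node

    consider(all_idx, attach_root)
    n_splits = 0
    while frontier and n_splits < max_splits:
        # best gain; ties by lowest feature index, smallest threshold, creation order
        frontier.sort(key=lambda e: (-e[0], e[1], e[2], e[3]))
        gain, j, thr, _, idx, attach = frontier.pop(0)
        left_idx = idx[X[idx, j] < thr]
        right_idx = idx[X[idx, j] >= thr]
        node = TreeNode(predictors[j], float(thr), make_leaf(left_idx), make_leaf(right_idx))
        node.n = int(idx.size)
        attach(node)
        n_splits += 1

        def attach_left(child, node=node):
            node.left = child

        def attach_right(child, node=node):
            node.right = child

        consider(left_idx, attach_left)
        consider(right_idx, attach_right)

    return DecisionTree(root=root_holder[0], predictors=tuple(predictors))


def predict(tree: DecisionTree, features: SubjectFeatures | Mapping[str, float]) -> tuple[bool, float]:
    """Route a subject through a tree; returns (label, positive fraction)."""
    return tree.decide(features)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def metrics(cm: ConfusionMatrix) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, accuracy); ``None`` marks an undefined
    metric (zero denominator) rather than propagating NaN."""
    sens = cm.TP / (cm.TP + cm.FN) if (cm.TP + cm.FN) > 0 else None
    spec = cm.TN / (cm.TN + cm.FP) if (cm.TN + cm.FP) > 0 else None
    acc = (cm.TP + cm.TN) / cm.total if cm.total > 0 else None
    return sens, spec, acc


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> tuple[list[tuple[float, float, float]], float]:
    """ROC by sweeping all distinct score thresholds, AUC by trapezoid.

    Ties are grouped at one threshold, so the trapezoidal area equals the
    Mann-Whitney rank statistic (probability a random positive outscores
    a random negative, ties counted half).  Requires both classes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    points: list[tuple[float, float, float]] = [(0.0, 0.0, float("inf"))]
    tp = fp = 0
    i = 0
    auc = 0.0
    while i < s_sorted.size:
        j = i
        while j < s_sorted.size and s_sorted[j] == s_sorted[i]:
            j += 1
        dtp = int(y_sorted[i:j].sum())
        dfp = (j - i) - dtp
        prev_tpr, prev_fpr = tp / n_pos, fp / n_neg
        tp += dtp
        fp += dfp
        tpr, fpr = tp / n_pos, fp / n_neg
        auc += (fpr - prev_fpr) * (tpr + prev_tpr) / 2.0
        points.append((fpr, tpr, float(s_sorted[i])))
        i = j
    return points, float(auc)


def loocv(
    table: Sequence[SubjectFeatures],
    predictors: Sequence[str],
    constraints: CartConstraints | None = None,
) -> list[tuple[str, float, bool, bool]]:
    """Leave-one-out cross-validation of the constrained CART.

    Trains exactly ``n`` trees, each with one subject held out, and
    records that subject's held-out (score, predicted, truth).  The
    partitions are the subjects themselves, so the output is invariant to
    input ordering (results are returned in input order, but each entry
    depends only on the subject set).  A fold whose training split is
    single-class trains a single-leaf tree.
    """
    n = len(table)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    out = []
    for i, subject in enumerate(table):
        train = [s for j, s in enumerate(table) if j != i]
        tree = train_cart(train, predictors, constraints)
        label, score = tree.decide(subject)
        out.append((subject.subject_id, float(score), bool(label), bool(subject.label)))
    return out


def confusion_from_predictions(pairs: Sequence[tuple[str, float, bool, bool]]) -> ConfusionMatrix:
    """Pool per-subject (id, score, predicted, truth) into one matrix."""
    tp = sum(1 for _, _, p, t in pairs if p and t)
    fp = sum(1 for _, _, p, t in pairs if p and not t)
    tn = sum(1 for _, _, p, t in pairs if not p and not t)
    fn = sum(1 for _, _, p, t in pairs if not p and t)
    return ConfusionMatrix(TP=tp, FP=fp, TN=tn, FN=fn)


@dataclass
class ScreeningReport:
    """Pooled evaluation summary of one classifier on one cohort."""

    confusion: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    auc: float | None
    roc_points: list[tuple[float, float, float]]
    per_subject: list[tuple[str, float, bool, bool]]

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.confusion.TP, "FP": self.confusion.FP,
                          "TN": self.confusion.TN, "FN": self.confusion.FN},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "roc_points": [[fpr, tpr, thr if np.isfinite(thr) else None]
                           for fpr, tpr, thr in self.roc_points],
            "per_subject": [
                {"subject_id": sid, "score": sc, "predicted": bool(p), "truth": bool(t)}
                for sid, sc, p, t in self.per_subject
            ],
        }


def evaluate_loocv(
    table: Sequence[SubjectFeatures],
    predictors: Sequence[str],
    constraints: CartConstraints | None = None,
) -> ScreeningReport:
    """LOOCV the constrained CART and pool results into one report."""
    pairs = loocv(table, predictors, constraints)
    cm = confusion_from_predictions(pairs)
    sens, spec, acc = metrics(cm)
    scores = [p[1] for p in pairs]
    truths = [p[3] for p in pairs]
    try:
        roc, auc = roc_auc(scores, truths)
    except ValueError:
        roc, auc = [], None
    return ScreeningReport(cm, sens, spec, acc, auc, roc, pairs)
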