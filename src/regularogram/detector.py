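"""Explainable AF detection: a split-capped decision tree over the index triple.

The classifier's job is to demarcate the irregular irregularity zone, not
to squeeze out performance: an axis-aligned binary decision tree over
(variability, normality, mean RR) is non-linear, fast and readable.  Growth
is capped at a maximum number of internal splits (default 30) to avoid
overfitting; each split is a single axis-parallel line in the feature
space, so a 4-split tree can carve out a rectangle of the RGG plane.

The evaluation and selection protocol mirrors clinical practice:

* ``evaluate`` — confusion counts plus sensitivity, specificity, PPV, NPV,
  accuracy and F1; ratios with a zero denominator are reported as absent
  (an all-negative test set yields only Sp and ACC).
* ``cross_validate`` — record-level k-fold over a (MESC order, window
  length) grid, best cell by mean validation accuracy, runners-up compared
  to the best by a one-tailed unpaired t-test.
* ``patient_to_self`` — chronological train/holdout split within each
  record, sweeping the split cap.
* ``cross_database`` — train on one named cohort, test on the others.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .indices import IndexConfig, WindowIndexRecord, compute_indices

__all__ = [
    "TreeModel",
    "MetricsReport",
    "ValidationResult",
    "CrossDatabaseResult",
    "train_tree",
    "evaluate",
    "cross_validate",
    "patient_to_self",
    "cross_database",
]

FEATURE_NAMES = ("variability", "normality", "mean_rr")


@dataclass
class TreeModel:
    """An axis-aligned binary split tree with a cap on internal nodes.

    Stored as parallel node arrays (sklearn layout): ``feature[i] < 0``
    marks a leaf predicting ``leaf_label[i]``; otherwise node ``i`` routes
    ``x[feature[i]] <= threshold[i]`` to ``left[i]``, else ``right[i]``.
    """

    feature: list[int]
    threshold: list[float]
    left: list[int]
    right: list[int]
    leaf_label: list[str | None]
    max_splits: int
    n_features: int = 3
    provenance: dict = field(default_factory=dict)

    @property
    def n_internal_nodes(self) -> int:
        return sum(1 for f in self.feature if f >= 0)

    def predict(self, features) -> list[str]:
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected feature arity {self.n_features}, "
                             f"got shape {X.shape}")
        out = []
        for row in X:
            i = 0
            while self.feature[i] >= 0:
                i = self.left[i] if row[self.feature[i]] <= self.threshold[i] \
                    else self.right[i]
            out.append(self.leaf_label[i])
        return out

    def to_json(self, path=None) -> str:
        doc = {"feature": self.feature, "threshold": self.threshold,
               "left": self.left, "right": self.right,
               "leaf_label": self.leaf_label, "max_splits": self.max_splits,
               "n_features": self.n_features, "provenance": self.provenance}
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TreeModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls(**doc)


def train_tree(features, labels, max_splits: int = 30,
               provenance: dict | None = None) -> TreeModel:
    """Fit a Gini-impurity tree grown best-first up to ``max_splits`` splits.

    A binary tree with k internal nodes has k+1 leaves, so the cap is
    enforced through the leaf count.  Minimum leaf size 1, no pruning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if max_splits < 1:
        raise ValueError("max_splits must be at least 1")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    clf = DecisionTreeClassifier(criterion="gini",
                                 max_leaf_nodes=max_splits + 1,
                                 random_state=0)
    clf.fit(X, y)
    t = clf.tree_
    classes = clf.classes_
    leaf_label: list[str | None] = []
    for i in range(t.node_count):
        if t.children_left[i] < 0:
            leaf_label.append(str(classes[int(np.argmax(t.value[i]))]))
        else:
            leaf_label.append(None)
    model = TreeModel(
        feature=[int(f) if t.children_left[i] >= 0 else -1
                 for i, f in enumerate(t.feature)],
        threshold=[float(th) for th in t.threshold],
        left=[int(c) for c in t.children_left],
        right=[int(c) for c in t.children_right],
        leaf_label=leaf_label,
        max_splits=max_splits,
        n_features=X.shape[1],
        provenance=provenance or {},
    )
    assert model.n_internal_nodes <= max_splits
    return model


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the six standard clinical metrics.

    Metrics whose denominator is zero are ``None`` (absent), as for a test
    set with no positive windows, where only specificity and accuracy are
    defined.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    f1: float | None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def evaluate(pred_labels, true_labels, positive: str = "AF") -> MetricsReport:
    """Tally confusion counts and derive the clinical metrics.

    Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    ACC = (TP+TN)/(TP+TN+FP+FN), F1 = 2TP/(2TP+FP+FN).
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("prediction and truth must be equal-length and non-empty")
    p, t = pred == positive, true == positive
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def _records_to_xy(records: list[WindowIndexRecord]):
    X = np.array([r.features for r in records], dtype=float)
    y = np.array([r.label for r in records])
    return X, y


@dataclass
class ValidationResult:
    """Hyperparameter grid outcome of record-level cross-validation."""

    grid: dict            # (order, window_length) -> mean validation accuracy
    fold_accuracies: dict  # (order, window_length) -> per-fold accuracies
    best: tuple[int, int]
    p_values: dict        # cell -> one-tailed p vs the best cell
    folds: int
    fold_assignment: np.ndarray = None  # fold index per input record


def _one_tailed_p(best: np.ndarray, other: np.ndarray) -> float:
    """One-tailed unpaired t-test that the best cell's mean exceeds the other's."""
    res = stats.ttest_ind(best, other, alternative="greater")
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups
        if np.mean(best) > np.mean(other):
            return np.finfo(float).tiny
        return 0.5
    return p


def cross_validate(dataset, orders, window_lengths, folds: int = 5,
                   seed: int = 0, stride: int | None = None,
                   max_splits: int = 30) -> ValidationResult:
    """Select (MESC order, window length) by record-level k-fold accuracy.

    ``dataset`` is a list of (RRSeries, segments) records.  Whole records
    are assigned to folds so that no record contributes windows to both the
    training and validation side of any fold (no leakage).  Each non-best
    cell is compared to the best by a one-tailed unpaired t-test over fold
    accuracies (significant at p < 0.05).
    """
    n_records = len(dataset)
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if n_records <= folds:
        raise ValueError("need more records than folds")
    rng = np.random.default_rng(seed)
    fold_of = rng.permuted(np.arange(n_records) % folds)

    fold_accs: dict[tuple[int, int], np.ndarray] = {}
    for order in orders:
        for wlen in window_lengths:
            cfg = IndexConfig(mesc_order=order, window_length=wlen,
                              stride=stride if stride is not None else max(1, wlen // 5))
            per_record = [compute_indices(rr, segs, cfg) for rr, segs in dataset]
            accs = []
            for k in range(folds):
                train = [r for i, recs in enumerate(per_record) if fold_of[i] != k
                         for r in recs]
                val = [r for i, recs in enumerate(per_record) if fold_of[i] == k
                       for r in recs]
                if not train or not val:
                    raise ValueError(f"degenerate fold {k}: empty train or validation side")
                Xtr, ytr = _records_to_xy(train)
                Xva, yva = _records_to_xy(val)
                model = train_tree(Xtr, ytr, max_splits=max_splits)
                accs.append(evaluate(model.predict(Xva), yva).accuracy)
            fold_accs[(order, wlen)] = np.array(accs, dtype=float)

    grid = {cell: float(np.mean(a)) for cell, a in fold_accs.items()}
    best = max(grid, key=lambda c: (grid[c], (-c[0], -c[1])))
    p_values = {cell: _one_tailed_p(fold_accs[best], fold_accs[cell])
                for cell in grid if cell != best}
    return ValidationResult(grid=grid, fold_accuracies=fold_accs, best=best,
                            p_values=p_values, folds=folds,
                            fold_assignment=fold_of)


def patient_to_self(record_indices: list[list[WindowIndexRecord]],
                    split_caps=(2, 3, 4, 10, 20, 30),
                    holdout_fraction: float = 0.3, seed: int = 0):
    """Within-record chronological train/holdout evaluation, sweeping the cap.

    For each record the first (1 - holdout_fraction) of its windows (in
    time order) train the tree and the rest are held out.  Records whose
    training part lacks one of the classes are skipped and reported.
    Returns (dict cap -> mean holdout accuracy, list of skipped record ids).
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    per_cap: dict[int, list[float]] = {cap: [] for cap in split_caps}
    skipped: list[str] = []
    for recs in record_indices:
        if not recs:
            continue
        recs = sorted(recs, key=lambda r: r.window.start_beat)
        cut = int(round(len(recs) * (1 - holdout_fraction)))
        train, hold = recs[:cut], recs[cut:]
        if not hold or len({r.label for r in train}) < 2:
            skipped.append(recs[0].record_id)
            continue
        Xtr, ytr = _records_to_xy(train)
        Xho, yho = _records_to_xy(hold)
        for cap in split_caps:
            model = train_tree(Xtr, ytr, max_splits=cap)
            per_cap[cap].append(evaluate(model.predict(Xho), yho).accuracy)
    if skipped:
        warnings.warn(f"records skipped (single class in training part): {skipped}")
    return ({cap: float(np.mean(a)) if a else float("nan")
             for cap, a in per_cap.items()}, skipped)


@dataclass
class CrossDatabaseResult:
    """Cross-cohort generalization outcome.

    ``train_report`` re-evaluates the model on its own training windows and
    is flagged optimistic — it indicates successful training only.
    """

    model: TreeModel
    train_name: str
    train_report: MetricsReport
    optimistic: tuple[str, ...]
    test_reports: dict[str, MetricsReport]


def cross_database(train_set: tuple[str, list[list[WindowIndexRecord]]],
                   test_sets: dict[str, list[list[WindowIndexRecord]]],
                   max_splits: int = 30) -> CrossDatabaseResult:
    """Train one tree on a full cohort and test it on disjoint cohorts."""
    train_name, train_records = train_set
    train_flat = [r for recs in train_records for r in recs]
    train_ids = {r.record_id for r in train_flat}
    for name, recs_list in test_sets.items():
        ids = {r.record_id for recs in recs_list for r in recs}
        if train_ids & ids:
            raise ValueError(f"record ids shared between train set and {name!r}: "
                             f"{sorted(train_ids & ids)[:3]}")
    Xtr, ytr = _records_to_xy(train_flat)
    model = train_tree(Xtr, ytr, max_splits=max_splits,
                       provenance={"train_set": train_name,
                                   "max_splits": max_splits})
    train_report = evaluate(model.predict(Xtr), ytr)
    test_reports = {}
    for name, recs_list in test_sets.items():
        flat = [r for recs in recs_list for r in recs]
        X, y = _records_to_xy(flat)
        test_reports[name] = evaluate(model.predict(X), y)
    return CrossDatabaseResult(model=model, train_name=train_name,
                               train_report=train_report,
                               optimistic=(train_name,),
                               test_reports=test_reports)
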