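"""Random-forest discrimination of tissue grades under stratified 5-fold CV.

A 100-tree random forest is trained per fold on the z-scored feature table
and evaluated on the held-out fold.  For a 4-class problem the per-class
metrics are computed one-vs-rest from the predicted labels
(accuracy/sensitivity/specificity) and from the out-of-fold class
probability scores (ROC/AUC); fold-level metrics are macro-averaged across
classes and then summarized as mean +/- SD over folds.  Plain multiclass
accuracy is reported alongside.

Feature subsets — a single octant's 3 quantifiers, a single quantifier's 8
octants, or all 24 features — reproduce the per-band / per-quantifier
experiment grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES
from .wavelet import OCTANT_KEYS

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "stratified_kfold",
    "confusion_metrics",
    "roc_auc",
    "train_eval_cv",
    "octant_feature_subset",
    "quantifier_feature_subset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN marks an undefined metric."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion counts")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return accuracy, sensitivity, specificity


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) per sample, stratified by class label.

    Folds partition the samples and per-class counts across folds differ by
    at most one.  Classes with fewer than k samples are simply spread over
    as many folds as they have samples; a rotating fold offset between
    classes keeps overall fold sizes balanced.  A fixed seed reproduces the
    assignment exactly.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.full(labels.size, -1, dtype=int)
    offset = 0
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        assignment[idx] = (offset + np.arange(idx.size)) % k
        offset = (offset + idx.size) % k
    return assignment


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC with ROC curve points for binary labels and real-valued scores.

    The AUC is the Mann-Whitney pairwise-concordance probability (ties count
    one half); the returned (fpr, tpr) points trace the empirical ROC curve
    whose trapezoidal integral equals it.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an ROC")
    pos, neg = s[y], s[~y]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    last_of_threshold = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[last_of_threshold] / n_pos]
    fpr = np.r_[0.0, fps[last_of_threshold] / n_neg]
    return float(auc), fpr, tpr


def octant_feature_subset(octant: str) -> tuple[str, ...]:
    """The 3 quantifier features of one octant sub-band."""
    if octant not in OCTANT_KEYS:
        raise ValueError(f"unknown octant {octant!r}")
    return tuple(n for n in FEATURE_NAMES if n.endswith(f"_{octant}"))


def quantifier_feature_subset(quantifier: str) -> tuple[str, ...]:
    """The 8 octant features of one quantifier (variance/entropy/energy)."""
    subset = tuple(n for n in FEATURE_NAMES if n.startswith(f"{quantifier}_"))
    if not subset:
        raise ValueError(f"unknown quantifier {quantifier!r}")
    return subset


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validated classifier metrics."""

    fold_assignment: np.ndarray
    per_fold: pd.DataFrame  # fold, accuracy, sensitivity, specificity, multiclass_accuracy
    per_class_auc: pd.DataFrame  # class, fold, auc
    features: tuple[str, ...]
    k: int
    n_trees: int
    seed: int
    rf_params: dict = field(default_factory=dict)

    def _agg(self, col: str) -> tuple[float, float]:
        v = self.per_fold[col].to_numpy(dtype=float)
        return float(np.nanmean(v)), float(np.nanstd(v))

    @property
    def accuracy(self) -> tuple[float, float]:
        """Mean +/- SD over folds of macro-averaged one-vs-rest accuracy."""
        return self._agg("accuracy")

    @property
    def sensitivity(self) -> tuple[float, float]:
        return self._agg("sensitivity")

    @property
    def specificity(self) -> tuple[float, float]:
        return self._agg("specificity")

    @property
    def multiclass_accuracy(self) -> tuple[float, float]:
        """Mean +/- SD over folds of the plain fraction of correct labels."""
        return self._agg("multiclass_accuracy")

    def mean_auc(self) -> dict[str, float]:
        """Fold-averaged one-vs-rest AUC per class."""
        return self.per_class_auc.groupby("class")["auc"].mean().to_dict()

    def summary(self) -> dict:
        acc, acc_sd = self.accuracy
        sens, sens_sd = self.sensitivity
        spec, spec_sd = self.specificity
        mc, mc_sd = self.multiclass_accuracy
        return {
            "k": self.k,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "features": list(self.features),
            "accuracy_mean": acc, "accuracy_sd": acc_sd,
            "sensitivity_mean": sens, "sensitivity_sd": sens_sd,
            "specificity_mean": spec, "specificity_sd": spec_sd,
            "multiclass_accuracy_mean": mc, "multiclass_accuracy_sd": mc_sd,
            "auc_per_class": self.mean_auc(),
        }


def train_eval_cv(
    table: pd.DataFrame,
    features: tuple[str, ...] | None = None,
    k: int = 5,
    n_trees: int = 100,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold random-forest evaluation of a feature table.

    Per fold, a forest of ``n_trees`` trees (sqrt-p features per split,
    unlimited depth) is fitted on the training rows and scored on the test
    rows; one-vs-rest confusion metrics come from predicted labels, AUC from
    the held-out class-probability scores.
    """
    features = tuple(features) if features is not None else FEATURE_NAMES
    if len(features) == 0:
        raise ValueError("empty feature subset")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    labels = table["label"].to_numpy()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    X = table.loc[:, list(features)].to_numpy(dtype=float)

    assignment = stratified_kfold(labels, k=k, seed=seed)
    fold_rows = []
    auc_rows = []
    for fold in range(k):
        test = assignment == fold
        train = ~test
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed + fold,
        )
        rf.fit(X[train], labels[train])
        pred = rf.predict(X[test])
        proba = rf.predict_proba(X[test])
        y_test = labels[test]

        accs, senss, specs = [], [], []
        for c in classes:
            pos = y_test == c
            hat = pred == c
            counts = ConfusionCounts(
                tp=int((pos & hat).sum()),
                tn=int((~pos & ~hat).sum()),
                fp=int((~pos & hat).sum()),
                fn=int((pos & ~hat).sum()),
            )
            a, sn, sp = confusion_metrics(counts)
            accs.append(a)
            senss.append(sn)
            specs.append(sp)
            if c in rf.classes_ and pos.any() and (~pos).any():
                score = proba[:, list(rf.classes_).index(c)]
                auc, _, _ = roc_auc(score, pos)
                auc_rows.append({"class": c, "fold": fold, "auc": auc})
        fold_rows.append(
            {
                "fold": fold,
                "accuracy": float(np.nanmean(accs)),
                "sensitivity": float(np.nanmean(senss)),
                "specificity": float(np.nanmean(specs)),
                "multiclass_accuracy": float((pred == y_test).mean()),
            }
        )

    return CVReport(
        fold_assignment=assignment,
        per_fold=pd.DataFrame(fold_rows),
        per_class_auc=pd.DataFrame(auc_rows, columns=["class", "fold", "auc"]),
        features=features,
        k=k,
        n_trees=n_trees,
        seed=seed,
        rf_params={"max_features": "sqrt", "max_depth": None},
    )
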