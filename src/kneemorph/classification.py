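"""Tree-ensemble classification of the morphometric feature table.

Five feature selections (Bone #8, Cartilage #16, B-C #24, WT-C, TOT) are
fed to three tree-based learners (decision tree, random forest, gradient
boosting) under stratified 5-fold cross-validation; out-of-fold
predictions are pooled into one confusion matrix from which accuracy and
one-vs-rest sensitivity/specificity per class are computed.  Feature
importance (mean impurity decrease, normalized to percent) is reported
for the random forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)

BONE_FEATURES = [
    "FemurDENS", "FemurSTD", "TibiaDENS", "TibiaSTD",
    "PatellaDENS", "PatellaSTD", "PatellaVOL", "PatellaSURF",
]
CARTILAGE_FEATURES = [
    f"{c}{suffix}"
    for c in ("FemCart", "TibCartLat", "TibCartMed", "PatCart")
    for suffix in ("DENS", "STD", "VOL", "SURF")
]
SELECTIONS = ("Bone", "Cartilage", "B-C", "WT-C", "TOT")
ALGORITHMS = ("DT", "RF", "GB")

#: hyperparameters (the original analysis platform's defaults are unknown;
#: these ship as explicit config)
DEFAULT_HYPERPARAMS = {
    "DT": {"criterion": "gini"},
    "RF": {"n_estimators": 100},
    "GB": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
}


@dataclass
class ClassificationReport:
    """Pooled out-of-fold results of one (selection, algorithm) run."""

    algorithm: str
    selection: str
    classes: list[str]
    confusion: np.ndarray  # rows true, cols predicted
    accuracy: float  # percent
    sensitivity: dict[str, float]  # percent, per class
    specificity: dict[str, float]  # percent, one-vs-rest
    fold_assignments: np.ndarray
    seed: int
    importance: list[tuple[str, float]] | None = None  # (feature, percent)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "selection": self.selection,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "seed": self.seed,
            "importance": self.importance,
        }


def wtc_selection_columns(
    table: pd.DataFrame, unstable: Sequence[str] = ()
) -> list[str]:
    """WT-C columns eligible for classification: the 48-parameter block
    minus the 8 constant alpha (STDWeight) columns minus the configured
    unstable list."""
    from .wtc_features import wtc_column_names

    cols = [c for c in wtc_column_names() if not c.endswith("STDWeight")
            or c.endswith(("BelowSTDWeight", "AboveSTDWeight"))]
    cols = [c for c in cols if c not in unstable]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks WT-C columns: {missing[:5]}")
    return cols


def build_selection(
    table: pd.DataFrame, name: str, unstable: Sequence[str] = ()
) -> pd.DataFrame:
    """Column subset for one named feature selection.

    Hole-related features are never included (they are mostly zero and
    uninformative for classification).
    """
    if name == "Bone":
        cols = list(BONE_FEATURES)
    elif name == "Cartilage":
        cols = list(CARTILAGE_FEATURES)
    elif name == "B-C":
        cols = BONE_FEATURES + CARTILAGE_FEATURES
    elif name == "WT-C":
        cols = wtc_selection_columns(table, unstable)
    elif name == "TOT":
        cols = BONE_FEATURES + CARTILAGE_FEATURES + wtc_selection_columns(
            table, unstable
        )
    else:
        raise ValueError(f"unknown selection {name!r}; choose from {SELECTIONS}")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing[:5]}")
    return table[cols]


def _make_model(algorithm: str, seed: int, hyperparams: dict | None = None):
    params = dict(DEFAULT_HYPERPARAMS.get(algorithm, {}))
    if hyperparams:
        params.update(hyperparams)
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "GB":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def crossval_classify(
    features: pd.DataFrame,
    labels: Sequence[str],
    algorithm: str,
    k: int = 5,
    seed: int = 42,
    selection_name: str = "",
    hyperparams: dict | None = None,
) -> ClassificationReport:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    Deterministic for a fixed seed.  Classes smaller than k are allowed
    (folds are stratified as far as class counts permit); a class absent
    from some training fold is logged and prediction proceeds.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    classes = sorted(set(y))
    class_counts = {c: int((y == c).sum()) for c in classes}
    n_splits = min(k, min(class_counts.values())) if class_counts else k
    if n_splits < k:
        log.warning("reducing folds %d -> %d (smallest class has %d subjects)",
                    k, n_splits, min(class_counts.values()))
    if n_splits < 2:
        raise ValueError("smallest class too small for cross-validation")

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    folds = np.full(len(y), -1, dtype=np.int64)
    for fold, (train, test) in enumerate(skf.split(X, y)):
        if len(set(y[train])) < len(classes):
            log.warning("fold %d training set misses a class", fold)
        model = _make_model(algorithm, seed, hyperparams)
        model.fit(X[train], y[train])
        pred[test] = model.predict(X[test])
        folds[test] = fold

    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y, pred):
        confusion[idx[t], idx[p]] += 1
    accuracy = 100.0 * np.trace(confusion) / len(y)
    sensitivity, specificity = {}, {}
    for c in classes:
        i = idx[c]
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = confusion.sum() - tp - fn - fp
        sensitivity[c] = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
        specificity[c] = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")

    report = ClassificationReport(
        algorithm=algorithm,
        selection=selection_name,
        classes=classes,
        confusion=confusion,
        accuracy=float(accuracy),
        sensitivity=sensitivity,
        specificity=specificity,
        fold_assignments=folds,
        seed=seed,
    )
    if algorithm == "RF":
        model = _make_model("RF", seed, hyperparams)
        model.fit(X, y)
        report.importance = feature_importance(model, list(features.columns))
    return report


def feature_importance(
    model: RandomForestClassifier, feature_names: Sequence[str]
) -> list[tuple[str, float]]:
    """Mean impurity-decrease importances as percentages summing to 100,
    ranked descending."""
    imp = np.asarray(model.feature_importances_, dtype=np.float64)
    total = imp.sum()
    if total == 0:
        pct = np.full_like(imp, 100.0 / len(imp))
    else:
        pct = 100.0 * imp / total
    order = np.argsort(pct)[::-1]
    return [(feature_names[i], float(pct[i])) for i in order]


def run_all_classifications(
    table: pd.DataFrame,
    labels: Sequence[str],
    k: int = 5,
    seed: int = 42,
    unstable: Sequence[str] = (),
    hyperparams: dict | None = None,
) -> list[ClassificationReport]:
    """All 5 selections x 3 algorithms (15 reports)."""
    reports = []
    for sel in SELECTIONS:
        sub = build_selection(table, sel, unstable)
        for alg in ALGORITHMS:
            hp = (hyperparams or {}).get(alg)
            reports.append(
                crossval_classify(sub, labels, alg, k=k, seed=seed,
                                  selection_name=sel, hyperparams=hp)
            )
    return reports
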