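"""Classifier evaluation, window-length sweep, feature ablation, explanation.

Evaluation design: stratified 80/20 train-test split; 6-fold cross-validated
accuracy on the training portion reported as validation accuracy; the model
refit on the full training split is scored on the held-out 20% (accuracy,
macro precision/recall/F1, confusion matrix).  Overlapping windows from one
trial may land on both sides of the split under the default window-level
split; grouping="by_trial" keeps all windows of a contiguous stimulus
segment on one side for a leakage-free evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .bands import DEFAULT_BANDS
from .errors import ConfigurationError
from .features import WindowSpec, extract_features, feature_columns
from .recording import Recording
from .vmd import VMDConfig

__all__ = [
    "SplitSpec",
    "CVSpec",
    "ModelSpec",
    "EvalReport",
    "ImportanceReport",
    "build_model",
    "split_data",
    "train_eval",
    "sweep_windows",
    "ablation_table",
    "explain",
]

MODEL_KINDS = ("KNN", "SVM", "DT", "RF")


@dataclass
class SplitSpec:
    """Train/test partition: fraction, stratification, optional grouping."""

    train_frac: float = 0.8
    stratified: bool = True
    seed: int = 0
    grouping: str = "none"  # "none" | "by_trial"

    def __post_init__(self) -> None:
        if not (0 < self.train_frac < 1):
            raise ConfigurationError("train_frac must lie in (0, 1)")
        if self.grouping not in ("none", "by_trial"):
            raise ConfigurationError("grouping must be 'none' or 'by_trial'")


@dataclass
class CVSpec:
    """k-fold cross-validation on the training split."""

    n_folds: int = 6
    shuffled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")


@dataclass
class ModelSpec:
    """Classifier family and hyperparameters.

    Defaults: KNN k=5 Euclidean; SVM RBF C=1 gamma='scale'; decision tree
    with Gini impurity and unlimited depth; random forest of 100 trees with
    sqrt(n_features) candidates per split.
    """

    kind: str = "RF"
    params: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = self.kind.upper()
        if self.kind not in MODEL_KINDS:
            raise ConfigurationError(f"model kind must be one of {MODEL_KINDS}")


@dataclass
class EvalReport:
    """Validation (CV) and held-out test metrics for one model."""

    model: ModelSpec
    validation_accuracy: float
    fold_scores: list[float]
    test_accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray  # rows = true class, alphabetical class order
    classes: list[str]
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "model": {"kind": self.model.kind, "params": dict(self.model.params)},
            "validation_accuracy": self.validation_accuracy,
            "fold_scores": self.fold_scores,
            "test_accuracy": self.test_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "classes": self.classes,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


@dataclass
class ImportanceReport:
    """Per-feature, per-class mean absolute attribution with a ranking."""

    method: str  # "tree_path" | "permutation"
    per_class: pd.DataFrame  # index = feature, columns = class names
    ranking: list[str]  # features, most important first

    def top(self, k: int = 6) -> list[str]:
        return self.ranking[:k]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "per_class": self.per_class.to_dict(),
            "ranking": self.ranking,
        }


def build_model(spec: ModelSpec):
    """Instantiate the sklearn estimator for a ModelSpec."""
    params = dict(spec.params)
    if spec.kind == "KNN":
        return KNeighborsClassifier(**{"n_neighbors": 5, **params})
    if spec.kind == "SVM":
        return SVC(**{"C": 1.0, "kernel": "rbf", "gamma": "scale", **params})
    if spec.kind == "DT":
        return DecisionTreeClassifier(
            **{"criterion": "gini", "random_state": spec.seed, **params}
        )
    return RandomForestClassifier(
        **{
            "n_estimators": 100,
            "max_features": "sqrt",
            "random_state": spec.seed,
            **params,
        }
    )


def _check_classes(labels: pd.Series) -> None:
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ConfigurationError("need at least two classes to split")
    if counts.min() < 2:
        raise ConfigurationError("need at least two rows per class")


def split_data(
    features: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified (optionally trial-grouped) train/test partition."""
    if spec is None:
        spec = SplitSpec()
    labels = features["label"]
    _check_classes(labels)
    if spec.grouping == "none":
        idx = np.arange(len(features))
        train_idx, test_idx = train_test_split(
            idx,
            train_size=spec.train_frac,
            stratify=labels if spec.stratified else None,
            random_state=spec.seed,
        )
    else:
        if "segment_id" not in features.columns:
            raise ConfigurationError("by_trial grouping needs a segment_id column")
        rng = np.random.default_rng(spec.seed)
        train_idx_l: list[int] = []
        test_idx_l: list[int] = []
        for cls in sorted(labels.unique()):
            segs = sorted(features.loc[labels == cls, "segment_id"].unique())
            if len(segs) < 2:
                raise ConfigurationError(
                    f"class {cls!r} has {len(segs)} trial(s); by_trial split needs >= 2"
                )
            segs = list(rng.permutation(segs))
            n_test = max(1, int(round((1 - spec.train_frac) * len(segs))))
            test_segs = set(segs[:n_test])
            mask = (labels == cls).to_numpy()
            in_test = features["segment_id"].isin(test_segs).to_numpy() & mask
            test_idx_l.extend(np.flatnonzero(in_test))
            train_idx_l.extend(np.flatnonzero(mask & ~in_test))
        train_idx, test_idx = np.array(sorted(train_idx_l)), np.array(sorted(test_idx_l))
    train = features.iloc[np.sort(train_idx)].reset_index(drop=True)
    test = features.iloc[np.sort(test_idx)].reset_index(drop=True)
    for part, name in ((train, "train"), (test, "test")):
        missing = set(labels.unique()) - set(part["label"].unique())
        if missing:
            raise ConfigurationError(f"class(es) {missing} absent from the {name} side")
    return train, test


def _xy(features: pd.DataFrame, columns: Sequence[str] | None = None):
    if columns is None:
        columns = [c for c in features.columns if c.startswith("IMF")]
    return features[list(columns)].to_numpy(), features["label"].to_numpy()


def cv_accuracy(
    train: pd.DataFrame,
    model_spec: ModelSpec,
    cv: CVSpec | None = None,
    columns: Sequence[str] | None = None,
) -> tuple[float, list[float]]:
    """Mean and per-fold stratified k-fold accuracy on a training table."""
    if cv is None:
        cv = CVSpec()
    X, y = _xy(train, columns)
    min_count = pd.Series(y).value_counts().min()
    if cv.n_folds > min_count:
        raise ConfigurationError(
            f"{cv.n_folds} folds exceed the smallest class count ({min_count})"
        )
    skf = StratifiedKFold(
        n_splits=cv.n_folds,
        shuffle=cv.shuffled,
        random_state=cv.seed if cv.shuffled else None,
    )
    scores = cross_val_score(build_model(model_spec), X, y, cv=skf, scoring="accuracy")
    return float(scores.mean()), [float(s) for s in scores]


def train_eval(
    features: pd.DataFrame,
    model: ModelSpec | None = None,
    split: SplitSpec | None = None,
    cv: CVSpec | None = None,
    columns: Sequence[str] | None = None,
) -> EvalReport:
    """Full evaluation: CV on the training split, then held-out test metrics."""
    if model is None:
        model = ModelSpec()
    train, test = split_data(features, split)
    val_acc, fold_scores = cv_accuracy(train, model, cv, columns)
    X_train, y_train = _xy(train, columns)
    X_test, y_test = _xy(test, columns)
    clf = build_model(model)
    clf.fit(X_train, y_train)
    y_pred = clf.predict(X_test)
    classes = sorted(set(y_train) | set(y_test))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_test, y_pred, labels=classes, average="macro", zero_division=0
    )
    return EvalReport(
        model=model,
        validation_accuracy=val_acc,
        fold_scores=fold_scores,
        test_accuracy=float(accuracy_score(y_test, y_pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        confusion=confusion_matrix(y_test, y_pred, labels=classes),
        classes=classes,
        n_train=len(train),
        n_test=len(test),
    )


def sweep_windows(
    recording: Recording,
    lengths_s: Sequence[float] = (1, 2, 3, 4, 15),
    models: Sequence[ModelSpec] | None = None,
    overlap_frac: float = 0.5,
    vmd: VMDConfig | None = None,
    split: SplitSpec | None = None,
    cv: CVSpec | None = None,
) -> pd.DataFrame:
    """Validation/test accuracy per (model, window length), as a tidy table.

    A failure in one cell (e.g. a window longer than any labeled segment)
    is recorded in that cell's ``error`` column; other cells are unaffected.
    """
    if models is None:
        models = [ModelSpec(kind=k) for k in MODEL_KINDS]
    rows = []
    for length in lengths_s:
        feats = None
        feat_error: str | None = None
        try:
            feats = extract_features(
                recording, WindowSpec(length_s=float(length), overlap_frac=overlap_frac), vmd
            )
        except Exception as exc:  # propagate per-cell with context
            feat_error = f"{type(exc).__name__}: {exc}"
        for model in models:
            row = {
                "model": model.kind,
                "window_s": float(length),
                "validation_accuracy": np.nan,
                "test_accuracy": np.nan,
                "error": "",
            }
            if feat_error is not None:
                row["error"] = feat_error
            else:
                try:
                    report = train_eval(feats, model, split, cv)
                    row["validation_accuracy"] = report.validation_accuracy
                    row["test_accuracy"] = report.test_accuracy
                except Exception as exc:
                    row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def ablation_table(
    features: pd.DataFrame,
    model: ModelSpec | None = None,
    split: SplitSpec | None = None,
    cv: CVSpec | None = None,
    n_modes: int = 5,
) -> pd.DataFrame:
    """CV validation accuracy per feature subset.

    Rows are IMF 1..n plus "All IMFs"; columns are the five bands plus
    "Combined features"; each cell trains on only that subset of the 25
    features, on one shared train split.
    """
    if model is None:
        model = ModelSpec()
    expected = feature_columns(n_modes)
    missing = [c for c in expected if c not in features.columns]
    if missing:
        raise ConfigurationError(f"feature matrix lacks columns: {missing[:5]} ...")
    train, _test = split_data(features, split)
    band_names = [b.name for b in DEFAULT_BANDS]
    row_labels = [f"IMF{k + 1}" for k in range(n_modes)] + ["All IMFs"]
    col_labels = band_names + ["Combined features"]
    table = pd.DataFrame(index=row_labels, columns=col_labels, dtype=float)
    for i, row_label in enumerate(row_labels):
        imfs = [i] if row_label != "All IMFs" else list(range(n_modes))
        for band in col_labels:
            bands = [band] if band != "Combined features" else band_names
            cols = [f"IMF{k + 1}_{b}" for k in imfs for b in bands]
            acc, _ = cv_accuracy(train, model, cv, cols)
            table.loc[row_label, band] = acc
    return table


def best_single_cell(table: pd.DataFrame) -> tuple[str, str]:
    """(IMF row, band column) of the best single-IMF single-band cell."""
    sub = table.iloc[:-1, :-1]
    flat = sub.stack()
    row, col = flat.idxmax()
    return str(row), str(col)


def _tree_path_attribution(clf, X: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    """Per-sample, per-feature, per-class path attribution for tree models.

    Walks each decision path and credits every split feature with the change
    in the node's class-probability value — the additive decomposition of a
    tree's prediction along its path, averaged over trees for a forest.
    """
    estimators = getattr(clf, "estimators_", [clf])
    n_samples, n_features = X.shape
    n_classes = len(classes)
    total = np.zeros((n_samples, n_features, n_classes))
    for tree_clf in estimators:
        tree = tree_clf.tree_
        value = tree.value.reshape(tree.node_count, -1)
        value = value / np.maximum(value.sum(axis=1, keepdims=True), 1e-300)
        node_indicator = tree_clf.decision_path(X)  # csr (n_samples, n_nodes)
        indptr, indices = node_indicator.indptr, node_indicator.indices
        feature = tree.feature
        for s in range(n_samples):
            path = indices[indptr[s] : indptr[s + 1]]
            for parent, child in zip(path[:-1], path[1:]):
                total[s, feature[parent]] += value[child] - value[parent]
    return total / len(estimators)


def explain(
    model,
    features: pd.DataFrame,
    method: str = "tree_path",
    seed: int = 0,
    n_repeats: int = 20,
    columns: Sequence[str] | None = None,
) -> ImportanceReport:
    """Mean absolute per-class attribution for every feature.

    ``tree_path`` decomposes tree-ensemble probabilities along decision
    paths (fast, model-specific); ``permutation`` measures the mean absolute
    shift in predicted class scores when one feature column is shuffled
    (seeded, model-agnostic).  Both emit the same report schema.
    """
    if method not in ("tree_path", "permutation"):
        raise ConfigurationError("method must be 'tree_path' or 'permutation'")
    check_is_fitted(model)
    if columns is None:
        columns = [c for c in features.columns if c.startswith("IMF")]
    X = features[list(columns)].to_numpy()
    classes = [str(c) for c in model.classes_]

    if method == "tree_path":
        if not hasattr(model, "tree_") and not hasattr(model, "estimators_"):
            raise ConfigurationError("tree_path attribution needs a tree-based model")
        contrib = _tree_path_attribution(model, X, classes)
        attr = np.abs(contrib).mean(axis=0)  # (features, classes)
    else:
        rng = np.random.default_rng(seed)
        if hasattr(model, "predict_proba"):
            score = model.predict_proba
        else:
            def score(X_):  # one-hot of hard predictions
                pred = model.predict(X_)
                out = np.zeros((len(pred), len(classes)))
                for i, p in enumerate(pred):
                    out[i, classes.index(str(p))] = 1.0
                return out

        baseline = score(X)
        attr = np.zeros((X.shape[1], len(classes)))
        for j in range(X.shape[1]):
            acc = np.zeros_like(baseline)
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                acc += np.abs(score(Xp) - baseline)
            attr[j] = acc.mean(axis=0) / n_repeats

    per_class = pd.DataFrame(attr, index=list(columns), columns=classes)
    ranking = list(per_class.sum(axis=1).sort_values(ascending=False).index)
    return ImportanceReport(method=method, per_class=per_class, ranking=ranking)
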