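"""Gradient-boosted-tree behaviour classification.

Bursts are classified from their selected features with an XGBoost
multiclass model at the library's default hyperparameters (10 rounds,
depth 6, eta 0.3, gamma 0, colsample_bytree 1, min_child_weight 1,
subsample 1).  Evaluation follows two routes: a stratified 75/25 held-out
split, and a 5-fold cross-validated confusion matrix in which every burst
is predicted exactly once while held out, pooled into a single matrix with
per-class precision/recall and a Wilson 95% CI on overall accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint
from xgboost import XGBClassifier


@dataclass(frozen=True)
class Hyperparams:
    """Boosting hyperparameters (defaults = the library defaults used here)."""

    nrounds: int = 10
    max_depth: int = 6
    eta: float = 0.3
    gamma: float = 0.0
    colsample_bytree: float = 1.0
    min_child_weight: float = 1.0
    subsample: float = 1.0


DEFAULT_HYPERPARAMS = Hyperparams()


@dataclass
class FittedClassifier:
    """A trained multiclass boosted-tree model restricted to selected features.

    Holds the raw booster so persistence uses the boosting library's
    native JSON format; class labels, feature list, hyperparameters and
    seed live in a sidecar metadata file.
    """

    booster: xgboost.Booster
    features: list[str]
    classes: list[str]
    hyperparams: Hyperparams
    seed: int

    def save(self, model_path: str, meta_path: str) -> None:
        self.booster.save_model(model_path)
        Path(meta_path).write_text(
            json.dumps(
                {
                    "features": self.features,
                    "classes": self.classes,
                    "hyperparams": asdict(self.hyperparams),
                    "seed": self.seed,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, model_path: str, meta_path: str) -> "FittedClassifier":
        meta = json.loads(Path(meta_path).read_text())
        booster = xgboost.Booster()
        booster.load_model(model_path)
        return cls(
            booster=booster,
            features=meta["features"],
            classes=meta["classes"],
            hyperparams=Hyperparams(**meta["hyperparams"]),
            seed=meta["seed"],
        )


def _make_xgb(hp: Hyperparams, n_classes: int, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=hp.nrounds,
        max_depth=hp.max_depth,
        learning_rate=hp.eta,
        gamma=hp.gamma,
        colsample_bytree=hp.colsample_bytree,
        min_child_weight=hp.min_child_weight,
        subsample=hp.subsample,
        objective="multi:softprob" if n_classes > 2 else "binary:logistic",
        # exact splits fall midway between observed values, so held-out
        # points inside a class gap classify correctly
        tree_method="exact",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


def split_train_test(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test partition; returns (train_idx, test_idx).

    Classes with fewer than 2 members cannot be stratified; they are kept
    whole in the training set with a warning.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            warnings.warn(
                f"class {cls!r} has {len(idx)} member(s); kept whole in training set"
            )
            train_idx.extend(idx)
            continue
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def train(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    selected: list[str],
    hp: Hyperparams = DEFAULT_HYPERPARAMS,
    seed: int = 0,
) -> FittedClassifier:
    """Train the boosted-tree model on the selected feature columns only."""
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("training requires at least 2 behaviour classes")
    missing = set(selected) - set(features.columns)
    if missing:
        raise KeyError(f"selected features missing from matrix: {sorted(missing)}")
    y = np.searchsorted(classes, labels)
    model = _make_xgb(hp, len(classes), seed)
    model.fit(features[selected].to_numpy(), y)
    return FittedClassifier(
        booster=model.get_booster(),
        features=list(selected),
        classes=classes,
        hyperparams=hp,
        seed=seed,
    )


def _booster_class_index(booster: xgboost.Booster, X: np.ndarray) -> np.ndarray:
    probs = booster.predict(xgboost.DMatrix(X))
    if probs.ndim == 1:  # binary objective emits P(class 1)
        return (probs > 0.5).astype(int)
    return np.argmax(probs, axis=1)


def predict(model: FittedClassifier, features: pd.DataFrame) -> np.ndarray:
    """Predict one trained class label per burst row."""
    missing = set(model.features) - set(features.columns)
    if missing:
        raise KeyError(f"feature columns missing: {sorted(missing)}")
    if not len(features):
        return np.array([], dtype=object)
    idx = _booster_class_index(model.booster, features[model.features].to_numpy())
    return np.array(model.classes, dtype=object)[idx]


@dataclass(frozen=True)
class ConfusionReport:
    """Pooled confusion matrix: observed behaviours in columns, predicted in rows.

    ``precision[c]`` = correct / all predicted as c (row sums);
    ``recall[c]`` = correct / all observed as c (column sums);
    ``accuracy`` = trace / total, with a Wilson-score 95% CI.
    """

    classes: tuple[str, ...]
    matrix: np.ndarray  # predicted rows x observed columns
    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)
    accuracy: float = 0.0
    accuracy_ci: tuple[float, float] = (0.0, 1.0)

    @classmethod
    def from_labels(cls, observed, predicted, classes=None) -> "ConfusionReport":
        observed, predicted = np.asarray(observed), np.asarray(predicted)
        if classes is None:
            classes = sorted(set(observed) | set(predicted))
        classes = tuple(classes)
        lut = {c: i for i, c in enumerate(classes)}
        matrix = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for obs, pred in zip(observed, predicted):
            matrix[lut[pred], lut[obs]] += 1
        total = matrix.sum()
        correct = int(np.trace(matrix))
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = {
                c: float(matrix[i, i] / matrix[i, :].sum()) if matrix[i, :].sum() else np.nan
                for i, c in enumerate(classes)
            }
            rec = {
                c: float(matrix[i, i] / matrix[:, i].sum()) if matrix[:, i].sum() else np.nan
                for i, c in enumerate(classes)
            }
        lo, hi = proportion_confint(correct, total, alpha=0.05, method="wilson")
        return cls(
            classes=classes,
            matrix=matrix,
            precision=prec,
            recall=rec,
            accuracy=correct / total if total else np.nan,
            accuracy_ci=(float(lo), float(hi)),
        )

    def validate(self) -> None:
        """Assert internal consistency (recomputable from the matrix)."""
        m = self.matrix
        assert (m >= 0).all() and m.dtype.kind in "iu"
        total = m.sum()
        assert np.isclose(self.accuracy, np.trace(m) / total)
        for i, c in enumerate(self.classes):
            if m[i, :].sum():
                assert np.isclose(self.precision[c], m[i, i] / m[i, :].sum())
            if m[:, i].sum():
                assert np.isclose(self.recall[c], m[i, i] / m[:, i].sum())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.matrix, index=list(self.classes), columns=list(self.classes)
        )
        frame.index.name = "predicted"
        frame.columns.name = "observed"
        return frame


def cross_validate(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    selected: list[str],
    hp: Hyperparams = DEFAULT_HYPERPARAMS,
    folds: int = 5,
    seed: int = 0,
) -> ConfusionReport:
    """Stratified k-fold CV: each burst predicted once while held out.

    Fold predictions are pooled into a single confusion matrix so that the
    matrix total equals the input size.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if (counts < folds).any():
        warnings.warn(
            f"classes with fewer members than folds: "
            f"{counts[counts < folds].index.tolist()}"
        )
    classes = sorted(np.unique(labels).tolist())
    predicted = np.empty(len(labels), dtype=object)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    X = features[selected].to_numpy()
    y = np.searchsorted(classes, labels)
    for train_rows, val_rows in skf.split(X, y):
        model = _make_xgb(hp, len(np.unique(y[train_rows])), seed)
        fold_classes = np.unique(y[train_rows])
        model.fit(X[train_rows], np.searchsorted(fold_classes, y[train_rows]))
        predicted[val_rows] = np.array(classes, dtype=object)[
            fold_classes[model.predict(X[val_rows])]
        ]
    report = ConfusionReport.from_labels(labels, predicted, classes=classes)
    report.validate()
    return report
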