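"""Gradient-boosted tree behavior classifier: training, tuning, validation.

The classifier is a multiclass XGBoost ensemble (softmax objective).  Two
hyperparameter paths exist: ``"defaults"`` fixes the number of boosting
rounds at 10 (with ``colsample_bytree = min_child_weight = subsample = 1``
and library defaults otherwise), while ``"tune"`` grid-searches
``nrounds x max_depth x eta x gamma`` (240 combinations) scored by stratified
5-fold cross-validation repeated 3 times.

All splits and folds are stratified by behavior label: field datasets are
strongly unbalanced (rare behaviors may have under a hundred segments) and
plain random partitions could drop a class entirely.  Every source of
randomness takes an explicit seed and models run single-threaded, so results
are reproducible bit-for-bit.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xgboost
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    StratifiedKFold,
    train_test_split,
)

from .errors import (
    AlignmentError,
    DegenerateTaskError,
    ParameterError,
    SchemaError,
    StratificationError,
)

__all__ = [
    "Hyperparameters",
    "TrainedModel",
    "EvaluationReport",
    "hyperparameter_grid",
    "train_model",
    "tune_hyperparameters",
    "crossval_predictions",
    "evaluate",
    "predict_labels",
    "save_model",
    "load_model",
]

#: Tuning grid, row-major order: nrounds, max_depth, eta, gamma.
TUNE_GRID = {
    "nrounds": (5, 10, 50, 100),
    "max_depth": (2, 3, 4, 5, 6),
    "eta": (0.01, 0.1, 0.2, 0.3),
    "gamma": (0.0, 0.1, 0.5),
}


@dataclass(frozen=True)
class Hyperparameters:
    """XGBoost hyperparameters used throughout the package.

    The defaults freeze the library defaults (``max_depth=6, eta=0.3,
    gamma=0``) together with the fixed choices ``nrounds=10`` and
    ``colsample_bytree = min_child_weight = subsample = 1``.
    """

    nrounds: int = 10
    max_depth: int = 6
    eta: float = 0.3
    gamma: float = 0.0
    colsample_bytree: float = 1.0
    min_child_weight: float = 1.0
    subsample: float = 1.0

    def __post_init__(self) -> None:
        if self.nrounds < 1:
            raise ParameterError(f"nrounds must be >= 1, got {self.nrounds}")
        if not 0 < self.eta <= 1:
            raise ParameterError(f"eta must be in (0, 1], got {self.eta}")
        for name in ("subsample", "colsample_bytree"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1], got {v}")


def hyperparameter_grid() -> list[Hyperparameters]:
    """The full tuning grid in row-major (nrounds, max_depth, eta, gamma) order."""
    return [
        Hyperparameters(nrounds=nr, max_depth=md, eta=eta, gamma=g)
        for nr, md, eta, g in itertools.product(*TUNE_GRID.values())
    ]


def _make_classifier(
    hp: Hyperparameters, seed: int, n_classes: int = 3
) -> xgboost.XGBClassifier:
    # softmax multiclass objective; a two-class task uses the equivalent
    # logistic objective (the library rejects multi:softprob at num_class=2)
    multi = n_classes > 2
    return xgboost.XGBClassifier(
        n_estimators=hp.nrounds,
        max_depth=hp.max_depth,
        learning_rate=hp.eta,
        gamma=hp.gamma,
        colsample_bytree=hp.colsample_bytree,
        min_child_weight=hp.min_child_weight,
        subsample=hp.subsample,
        objective="multi:softprob" if multi else "binary:logistic",
        eval_metric="mlogloss" if multi else "logloss",
        # exact greedy splits land mid-gap between feature values, which the
        # histogram method does not guarantee; it is also fully deterministic
        tree_method="exact",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


@dataclass
class TrainedModel:
    """A fitted behavior classifier plus everything needed to reuse it.

    The ensemble is held as a plain :class:`xgboost.Booster`, which has a
    portable JSON serialization (see :func:`save_model`).
    """

    booster: xgboost.Booster
    feature_names: list[str]
    classes: list[str]  # index -> behavior name
    hyperparameters: Hyperparameters
    seed: int

    def predict(self, ft: pd.DataFrame) -> np.ndarray:
        return predict_labels(self, ft)


@dataclass
class EvaluationReport:
    """Confusion structure and summary statistics of a validation run.

    ``confusion`` holds predicted behaviors in rows and observed behaviors in
    columns; ``per_class`` holds one-vs-rest sensitivity, specificity,
    precision and balanced accuracy per behavior; ``importance`` holds
    per-feature gain shares summing to 1 (empty when not applicable).
    """

    confusion: pd.DataFrame
    accuracy: float
    kappa: float
    per_class: pd.DataFrame
    importance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "predicted": list(self.confusion.index),
                "observed": list(self.confusion.columns),
                "counts": self.confusion.to_numpy().tolist(),
            },
            "overall": {"accuracy": self.accuracy, "kappa": self.kappa},
            "per_class": self.per_class.to_dict(orient="index"),
            "importance": self.importance.to_dict(),
        }


def _as_labels(labels: Sequence[str]) -> np.ndarray:
    return np.asarray([str(l) for l in labels], dtype=object)


def _check_features(ft: pd.DataFrame) -> np.ndarray:
    X = ft.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    return X


def _encode(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    index = {c: i for i, c in enumerate(classes)}
    return np.asarray([index[l] for l in labels]), classes


def _check_class_sizes(labels: np.ndarray, k: int, what: str) -> None:
    names, counts = np.unique(labels, return_counts=True)
    small = [str(n) for n, c in zip(names, counts) if c < k]
    if small:
        raise StratificationError(
            f"class(es) {small} have fewer than {k} segments; cannot {what}"
        )


def evaluate(
    observed: Sequence[str], predicted: Sequence[str]
) -> EvaluationReport:
    """Confusion matrix, overall accuracy, Cohen's kappa and per-class
    statistics for a set of label predictions.

    The confusion matrix is tabulated over the union of the two label sets,
    predicted behaviors in rows and observed in columns.  Kappa is
    ``(p_o - p_e) / (1 - p_e)`` with the expected agreement ``p_e`` computed
    from the row/column marginals.  Per-class statistics are one-vs-rest;
    ratios with a zero denominator are reported as 0.
    """
    obs = _as_labels(observed)
    pred = _as_labels(predicted)
    if obs.shape != pred.shape or obs.size == 0:
        raise AlignmentError(
            f"observed ({obs.size}) and predicted ({pred.size}) must be "
            "non-empty and of equal length"
        )
    classes = sorted(set(obs) | set(pred))
    idx = {c: i for i, c in enumerate(classes)}
    m = len(classes)
    counts = np.zeros((m, m), dtype=int)
    for o, p in zip(obs, pred):
        counts[idx[p], idx[o]] += 1
    total = counts.sum()
    accuracy = float(np.trace(counts)) / total
    row = counts.sum(axis=1) / total  # predicted marginals
    col = counts.sum(axis=0) / total  # observed marginals
    p_e = float(np.dot(row, col))
    kappa = 1.0 if p_e == 1.0 else (accuracy - p_e) / (1.0 - p_e)
    stats = {}
    for c in classes:
        i = idx[c]
        tp = counts[i, i]
        fn = counts[:, i].sum() - tp
        fp = counts[i, :].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        stats[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "balanced_accuracy": (sens + spec) / 2.0,
        }
    confusion = pd.DataFrame(counts, index=classes, columns=classes)
    confusion.index.name = "predicted"
    confusion.columns.name = "observed"
    return EvaluationReport(
        confusion=confusion,
        accuracy=accuracy,
        kappa=float(kappa),
        per_class=pd.DataFrame(stats).T,
    )


def _gain_importance(
    est: xgboost.XGBClassifier, feature_names: Sequence[str]
) -> pd.Series:
    booster = est.get_booster()
    raw = booster.get_score(importance_type="total_gain")
    gains = np.zeros(len(feature_names))
    for i, name in enumerate(feature_names):
        gains[i] = raw.get(name, raw.get(f"f{i}", 0.0))
    total = gains.sum()
    if total > 0:
        gains = gains / total
    return pd.Series(gains, index=list(feature_names), name="gain_share")


def train_model(
    ft: pd.DataFrame,
    labels: Sequence[str],
    hyper_choice: str = "defaults",
    train_ratio: float = 0.75,
    seed: int = 0,
) -> tuple[TrainedModel, EvaluationReport]:
    """Train the behavior classifier and validate it on a held-out split.

    The dataset is split by label-stratified sampling at ``train_ratio``
    (default 0.75); the model is fit on the training part only and the
    returned :class:`EvaluationReport` is computed exclusively on the
    held-out part.  ``hyper_choice`` selects the fixed default
    hyperparameters (``nrounds=10``) or a grid-search tune (run, with
    repeated stratified CV, on the training part only).
    """
    if hyper_choice not in ("defaults", "tune"):
        raise ParameterError(f"hyper_choice must be 'defaults' or 'tune', got {hyper_choice!r}")
    if not 0 < train_ratio < 1:
        raise ParameterError(f"train_ratio must be in (0, 1), got {train_ratio}")
    y = _as_labels(labels)
    X = _check_features(ft)
    if len(y) != len(ft):
        raise AlignmentError(f"{len(ft)} feature rows but {len(y)} labels")
    if len(set(y)) < 2:
        raise DegenerateTaskError("need at least two behavior classes to train")
    _check_class_sizes(y, 2, "stratify a train/validation split")
    idx_train, idx_valid = train_test_split(
        np.arange(len(y)),
        train_size=train_ratio,
        stratify=y,
        random_state=seed,
    )
    missing = (set(y) - set(y[idx_train])) | (set(y) - set(y[idx_valid]))
    if missing:
        raise StratificationError(
            f"class(es) {sorted(missing)} absent from a partition"
        )
    if hyper_choice == "tune":
        hp = tune_hyperparameters(ft.iloc[idx_train], y[idx_train], seed=seed)
    else:
        hp = Hyperparameters()
    y_codes, classes = _encode(y)
    est = _make_classifier(hp, seed, len(classes))
    est.fit(X[idx_train], y_codes[idx_train])
    model = TrainedModel(
        booster=est.get_booster(),
        feature_names=list(ft.columns),
        classes=classes,
        hyperparameters=hp,
        seed=seed,
    )
    pred = np.asarray(classes, dtype=object)[est.predict(X[idx_valid])]
    report = evaluate(y[idx_valid], pred)
    report.importance = _gain_importance(est, model.feature_names)
    return model, report


def cv_accuracy(
    ft: pd.DataFrame,
    labels: Sequence[str],
    hp: Hyperparameters,
    seed: int,
    n_splits: int = 5,
    n_repeats: int = 1,
) -> float:
    """Mean accuracy of ``hp`` under seeded stratified k-fold CV (optionally
    repeated).  Shared scorer for feature selection and hyperparameter tuning."""
    y = _as_labels(labels)
    X = _check_features(ft)
    _check_class_sizes(y, n_splits, f"run {n_splits}-fold stratified CV")
    y_codes, classes = _encode(y)
    if n_repeats == 1:
        splitter: Iterable = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=seed
        ).split(X, y_codes)
    else:
        splitter = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=n_repeats, random_state=seed
        ).split(X, y_codes)
    accs = []
    for tr, va in splitter:
        est = _make_classifier(hp, seed, len(classes))
        est.fit(X[tr], y_codes[tr])
        accs.append(float(np.mean(est.predict(X[va]) == y_codes[va])))
    return float(np.mean(accs))


def tune_hyperparameters(
    ft: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    grid: Sequence[Hyperparameters] | None = None,
    n_splits: int = 5,
    n_repeats: int = 3,
) -> Hyperparameters:
    """Grid-search hyperparameters by repeated stratified cross-validation.

    Scores every combination of the grid (240 combinations by default) by
    mean accuracy over ``n_splits``-fold stratified CV repeated ``n_repeats``
    times, all seeded.  Ties break to the first grid point in row-major
    (nrounds, max_depth, eta, gamma) order.
    """
    candidates = list(grid) if grid is not None else hyperparameter_grid()
    if not candidates:
        raise ParameterError("hyperparameter grid is empty")
    best_hp, best_acc = None, -np.inf
    for hp in candidates:
        acc = cv_accuracy(ft, labels, hp, seed, n_splits=n_splits, n_repeats=n_repeats)
        if acc > best_acc:  # strict: ties keep the earlier grid point
            best_hp, best_acc = hp, acc
    return best_hp


def crossval_predictions(
    ft: pd.DataFrame,
    labels: Sequence[str],
    k: int = 5,
    seed: int = 0,
    hp: Hyperparameters | None = None,
) -> pd.DataFrame:
    """Out-of-fold predictions from seeded stratified k-fold cross-validation.

    Every segment appears exactly once as a validation case.  Returns a
    DataFrame aligned to the input rows with columns ``observed``,
    ``predicted`` and ``fold`` (1-based).
    """
    y = _as_labels(labels)
    X = _check_features(ft)
    if len(y) != len(ft):
        raise AlignmentError(f"{len(ft)} feature rows but {len(y)} labels")
    _check_class_sizes(y, k, f"run {k}-fold stratified CV")
    y_codes, classes = _encode(y)
    hp = hp or Hyperparameters()
    predicted = np.empty(len(y), dtype=object)
    fold_of = np.zeros(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, va) in enumerate(skf.split(X, y_codes), start=1):
        est = _make_classifier(hp, seed, len(classes))
        est.fit(X[tr], y_codes[tr])
        predicted[va] = np.asarray(classes, dtype=object)[est.predict(X[va])]
        fold_of[va] = fold
    return pd.DataFrame(
        {"observed": y, "predicted": predicted, "fold": fold_of}
    )


def predict_labels(model: TrainedModel, ft: pd.DataFrame) -> np.ndarray:
    """Predict one behavior name per feature-table row.

    The table must contain exactly the model's feature columns; order is
    normalized internally.  Missing or extra columns raise
    :class:`SchemaError` listing the difference.
    """
    want = set(model.feature_names)
    have = set(ft.columns)
    if want != have:
        raise SchemaError(
            f"feature mismatch: missing {sorted(want - have)}, "
            f"unexpected {sorted(have - want)}"
        )
    X = _check_features(ft[model.feature_names])
    probs = model.booster.inplace_predict(X, validate_features=False)
    if probs.ndim == 2:
        codes = np.argmax(probs, axis=1)  # ties -> lowest class index
    else:  # binary:logistic yields P(class 1); ties at 0.5 -> class 0
        codes = (probs > 0.5).astype(int)
    return np.asarray(model.classes, dtype=object)[codes]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a directory: the ensemble in XGBoost's
    portable JSON format plus a metadata sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    model.booster.save_model(path / "ensemble.json")
    meta = {
        "feature_names": model.feature_names,
        "classes": model.classes,
        "hyperparameters": asdict(model.hyperparameters),
        "seed": model.seed,
        "xgboost_version": xgboost.__version__,
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    booster = xgboost.Booster()
    booster.load_model(path / "ensemble.json")
    return TrainedModel(
        booster=booster,
        feature_names=list(meta["feature_names"]),
        classes=list(meta["classes"]),
        hyperparameters=Hyperparameters(**meta["hyperparameters"]),
        seed=int(meta["seed"]),
    )
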