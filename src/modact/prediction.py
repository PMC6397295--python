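"""Class prediction on module-activity profiles.

Trains Random Forest or SVM classifiers on modules x samples activity
matrices, assesses them by repeated stratified k-fold cross-validation
with rank-based AUC, and persists fitted models for later application.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DataError, ModelError
from .expression import Design
from .propagation import ActivityMatrix

__all__ = [
    "PredictorModel",
    "CVReport",
    "train_predictor",
    "predict",
    "save_model",
    "load_model",
    "rank_auc",
]

_FORMAT_MAGIC = "modact-predictor"
_FORMAT_VERSION = 1

# Defaults mirror the reference R implementations (randomForest: 500 trees,
# sqrt(p) features; e1071: RBF kernel, cost 1).
RF_PARAMS: dict = {"n_estimators": 500, "max_features": "sqrt"}
SVM_PARAMS: dict = {"kernel": "rbf", "C": 1.0, "gamma": "scale", "probability": True}


@dataclass
class CVReport:
    """Per-repeat, per-fold AUCs with summary statistics."""

    fold_aucs: np.ndarray  # shape (repeats, k)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1)) if self.fold_aucs.size > 1 else 0.0

    @property
    def median(self) -> float:
        return float(np.median(self.fold_aucs))

    @property
    def mad(self) -> float:
        return float(np.median(np.abs(self.fold_aucs - np.median(self.fold_aucs))))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fold_aucs,
            index=[f"repeat_{i + 1}" for i in range(self.fold_aucs.shape[0])],
            columns=[f"fold_{j + 1}" for j in range(self.fold_aucs.shape[1])],
        )
        return df


@dataclass
class PredictorModel:
    algorithm: str  # "rf" or "svm"
    classes: list[str]
    features: list[str]  # module ids, order fixed at training
    estimator: object
    metadata: dict = field(default_factory=dict)


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) formulation with midrank ties.

    ``y_true`` is boolean (positive class), ``scores`` the positive-class
    probability or score.
    """
    y_true = np.asarray(y_true, dtype=bool)
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _macro_ovr_auc(y: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    """Macro-averaged one-vs-rest AUC; equals binary AUC for 2 classes."""
    aucs = []
    for ci, c in enumerate(classes):
        mask = y == c
        if mask.all() or not mask.any():
            continue
        aucs.append(rank_auc(mask, proba[:, ci]))
    return float(np.mean(aucs)) if aucs else np.nan


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, **RF_PARAMS)
    if algorithm == "svm":
        return SVC(random_state=seed, **SVM_PARAMS)
    raise DataError(f"unknown algorithm {algorithm!r} (expected 'rf' or 'svm')")


def _design_xy(act: ActivityMatrix, design: Design) -> tuple[np.ndarray, np.ndarray, list[str]]:
    samples = [s for s in act.samples if s in design]
    X = act.data.loc[:, samples].to_numpy().T
    y = np.array([design[s] for s in samples])
    return X, y, samples


def _balanced_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Down-sample every class to the minority class size (seeded)."""
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(np.sort(idx))
    return np.sort(np.concatenate(keep))


def fit_classifier(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str = "rf",
    seed: int = 0,
    balance: bool = True,
):
    """Fit a single (optionally class-balanced) classifier. Used both for
    the final refit in :func:`train_predictor` and by the auto-KO search."""
    if len(np.unique(y)) < 2:
        raise ModelError("cannot train a predictor on a single class")
    if balance:
        idx = _balanced_indices(y, np.random.default_rng(seed))
        X, y = X[idx], y[idx]
    est = _make_estimator(algorithm, seed)
    est.fit(X, y)
    return est


def train_predictor(
    act: ActivityMatrix,
    design: Design,
    algorithm: str = "rf",
    k: int = 5,
    repeats: int = 50,
    seed: int = 0,
    balance: bool = True,
    resample_each_repeat: bool = True,
) -> tuple[PredictorModel, CVReport]:
    """Train a classifier on module activities and score it by repeated
    stratified k-fold CV.

    Class balancing down-samples the majority class (re-drawn each repeat
    by default).  Held-out AUC uses the rank formulation on class
    probabilities (macro one-vs-rest when >2 classes).  Fully
    deterministic given ``seed``.
    """
    if k < 2:
        raise DataError(f"k must be >= 2, got {k}")
    X_all, y_all, _ = _design_xy(act, design)
    classes, counts = np.unique(y_all, return_counts=True)
    if len(classes) < 2:
        raise DataError("need >= 2 classes to train a predictor")
    too_small = [f"{c} ({n})" for c, n in zip(classes, counts) if n < k]
    if too_small:
        raise DataError(f"every class needs >= k={k} samples; too small: {', '.join(too_small)}")

    rng = np.random.default_rng(seed)
    frozen_idx = _balanced_indices(y_all, rng) if (balance and not resample_each_repeat) else None
    fold_aucs = np.empty((repeats, k))
    for r in range(repeats):
        if balance:
            idx = frozen_idx if frozen_idx is not None else _balanced_indices(y_all, rng)
            X, y = X_all[idx], y_all[idx]
        else:
            X, y = X_all, y_all
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        for j, (tr, te) in enumerate(skf.split(X, y)):
            est = _make_estimator(algorithm, int(rng.integers(2**31 - 1)))
            est.fit(X[tr], y[tr])
            proba = est.predict_proba(X[te])
            fold_aucs[r, j] = _macro_ovr_auc(y[te], proba, est.classes_)

    final = fit_classifier(X_all, y_all, algorithm=algorithm, seed=seed, balance=balance)
    report = CVReport(fold_aucs=fold_aucs)
    model = PredictorModel(
        algorithm=algorithm,
        classes=[str(c) for c in final.classes_],
        features=list(act.modules),
        estimator=final,
        metadata={
            "k": k,
            "repeats": repeats,
            "seed": seed,
            "balance": balance,
            "resample_each_repeat": resample_each_repeat,
            "cv_mean_auc": report.mean,
        },
    )
    return model, report


def predict(model: PredictorModel, act: ActivityMatrix) -> pd.DataFrame:
    """Per-sample class probabilities (rows sum to 1).

    The activity matrix must contain every feature module used at
    training; extra modules are ignored.
    """
    missing = [m for m in model.features if m not in act.data.index]
    if missing:
        raise DataError(f"activity matrix is missing feature module(s): {missing}")
    if not act.samples:
        return pd.DataFrame(columns=model.classes)
    X = act.data.loc[model.features, :].to_numpy().T
    proba = model.estimator.predict_proba(X)
    proba = proba / proba.sum(axis=1, keepdims=True)
    return pd.DataFrame(proba, index=act.samples, columns=[str(c) for c in model.estimator.classes_])


def save_model(model: PredictorModel, path) -> None:
    payload = {"magic": _FORMAT_MAGIC, "format_version": _FORMAT_VERSION, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> PredictorModel:
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError, ImportError, IndexError) as e:
        raise ModelError(f"{path}: not a valid predictor file ({e})") from None
    if not isinstance(payload, dict) or payload.get("magic") != _FORMAT_MAGIC:
        raise ModelError(f"{path}: not a modact predictor file")
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ModelError(
            f"{path}: predictor format version {payload.get('format_version')} "
            f"not supported (expected {_FORMAT_VERSION})"
        )
    return payload["model"]
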