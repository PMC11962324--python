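"""Windowed classification heads.

Next-day emotional valence (3 classes) is predicted from a flattened window
of the w days of model outputs strictly before the target day; binarized
PHQ-9 items are predicted per question from one of three feature sources:
transformer decoder outputs ("embeddings"), decoder outputs concatenated
with predicted valence distributions ("embeddings+emotion"), or valence
distributions alone ("emotion").

Probability outputs of the tree ensembles are used directly as distributions
(no post-hoc calibration); the argmax is the forecast class.
"""

from __future__ import annotations

import hashlib
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALENCE_CLASSES = (0, 1, 2)
MODEL_KINDS = ("MLP", "RF", "XGB")


@dataclass
class FeatureWindowSet:
    """Flattened windows plus bookkeeping.

    ``X``: (N, w * D); ``y``: (N,); ``meta``: per-instance patient id and
    0-based target day index; ``skipped``: labeled days with insufficient or
    incomplete history.
    """

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame
    window: int
    skipped: int = 0


def build_windows(
    sources: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    window: int,
) -> FeatureWindowSet:
    """One instance per labeled day with ``window`` complete preceding days.

    ``sources`` maps patient id to a (T, D) per-day feature array (model
    outputs; rows may be NaN where the model has no prediction yet);
    ``labels`` maps patient id to a (T,) array with NaN on unlabeled days.
    The window covers days [t - window, t), never the target day itself.
    """
    X, y, meta = [], [], []
    skipped = 0
    for pid, lab in labels.items():
        if pid not in sources:
            continue
        src = np.asarray(sources[pid], dtype=float)
        lab = np.asarray(lab, dtype=float)
        T = min(len(src), len(lab))
        for t in np.flatnonzero(~np.isnan(lab[:T])):
            if t < window:
                skipped += 1
                continue
            win = src[t - window : t]
            if np.isnan(win).any():
                skipped += 1
                continue
            X.append(win.ravel())
            y.append(int(lab[t]))
            meta.append((pid, int(t)))
    if skipped:
        import logging

        logging.getLogger(__name__).info("build_windows: skipped %d labeled days", skipped)
    X_arr = np.asarray(X, dtype=float) if X else np.empty((0, window * next(iter(sources.values())).shape[1]))
    return FeatureWindowSet(
        X=X_arr,
        y=np.asarray(y, dtype=np.int64),
        meta=pd.DataFrame(meta, columns=["patient_id", "day"]),
        window=window,
        skipped=skipped,
    )


def _make_estimator(model_kind: str, seed: int, n_classes: int):
    if model_kind == "MLP":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(hidden_layer_sizes=(64,), max_iter=500, random_state=seed)
    if model_kind == "RF":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    if model_kind == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=300,
            max_depth=4,
            learning_rate=0.1,
            n_jobs=1,
            random_state=seed,
            tree_method="hist",
            verbosity=0,
        )
    raise ValueError(f"model_kind must be one of {MODEL_KINDS}")


@dataclass
class ValenceClassifier:
    """A fitted classifier emitting distributions over the three valence classes."""

    estimator: object
    classes_: np.ndarray
    window: int
    feature_dim: int
    fingerprint: str = ""

    def predict_distribution(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.feature_dim:
            raise ValueError(f"expected {self.feature_dim} features, got {X.shape[1]}")
        proba = self.estimator.predict_proba(X)
        full = np.zeros((len(X), len(VALENCE_CLASSES)))
        for j, c in enumerate(self.classes_):
            full[:, int(c)] = proba[:, j]
        return full

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_distribution(X).argmax(axis=1)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ValenceClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _fingerprint(window: int, dim: int, kind: str) -> str:
    return hashlib.sha256(f"{kind}:{window}:{dim}".encode()).hexdigest()[:16]


def train_valence(windows: FeatureWindowSet, model_kind: str = "XGB", seed: int = 0) -> ValenceClassifier:
    """Fit a 3-class valence classifier on feature windows.

    Requires at least two classes in the training labels. Deterministic given
    data and seed (tree ensembles run single-threaded).
    """
    classes = np.unique(windows.y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(model_kind, seed, len(classes))
    # xgboost requires labels encoded 0..n-1
    encoded = np.searchsorted(classes, windows.y)
    if model_kind in ("XGB", "RF"):
        # class-balanced weights: valence labels are imbalanced (negative
        # reports dominate) and macro metrics weight classes equally
        freq = np.bincount(encoded) / len(encoded)
        est.fit(windows.X, encoded, sample_weight=1.0 / freq[encoded])
    else:
        est.fit(windows.X, encoded)
    return ValenceClassifier(
        estimator=est,
        classes_=classes,
        window=windows.window,
        feature_dim=windows.X.shape[1],
        fingerprint=_fingerprint(windows.window, windows.X.shape[1], model_kind),
    )


def predict_valence(clf: ValenceClassifier, window: np.ndarray) -> np.ndarray:
    """Probability 3-vector over {negative, neutral, positive} for one window."""
    return clf.predict_distribution(np.asarray(window).ravel()[None, :])[0]


@dataclass
class PHQ9Classifiers:
    """Independent binary classifiers, one per answered PHQ-9 item."""

    estimators: dict[int, object] = field(default_factory=dict)
    window: int = 7
    feature_dim: int = 0
    source: str = "embeddings"

    def predict_proba(self, question: int, X: np.ndarray) -> np.ndarray:
        """P(high-frequency symptom) for each row of X."""
        if question not in self.estimators:
            raise KeyError(f"no classifier for question {question}")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        est = self.estimators[question]
        proba = est.predict_proba(X)
        if proba.shape[1] == 1:  # degenerate but guarded upstream
            return np.full(len(X), float(est.classes_[0]))
        return proba[:, list(est.classes_).index(1)]


def train_phq9(
    windows_per_question: dict[int, FeatureWindowSet],
    model_kind: str = "XGB",
    seed: int = 0,
    source: str = "embeddings",
) -> PHQ9Classifiers:
    """Fit one binary classifier per question; questions with fewer than 10
    labeled instances (or a single class) are skipped with a warning."""
    out = PHQ9Classifiers(source=source)
    for q, fw in sorted(windows_per_question.items()):
        if len(fw.y) < 10:
            warnings.warn(f"PHQ-9 question {q}: only {len(fw.y)} labeled instances, skipped", stacklevel=2)
            continue
        if len(np.unique(fw.y)) < 2:
            warnings.warn(f"PHQ-9 question {q}: single-class labels, skipped", stacklevel=2)
            continue
        est = _make_estimator(model_kind, seed + q, 2)
        est.fit(fw.X, fw.y)
        out.estimators[q] = est
        out.window = fw.window
        out.feature_dim = fw.X.shape[1]
    return out


def combine_sources(
    embeddings: dict[str, np.ndarray] | None,
    emotions: dict[str, np.ndarray] | None,
    source: str,
) -> dict[str, np.ndarray]:
    """Assemble the per-day feature table for a PHQ-9 feature configuration."""
    if source == "embeddings":
        if embeddings is None:
            raise ValueError("embeddings source requires embeddings")
        return embeddings
    if source == "emotion":
        if emotions is None:
            raise ValueError("emotion source requires emotion distributions")
        return emotions
    if source == "embeddings+emotion":
        if embeddings is None or emotions is None:
            raise ValueError("embeddings+emotion requires both sources")
        out = {}
        for pid in embeddings:
            if pid not in emotions:
                continue
            T = min(len(embeddings[pid]), len(emotions[pid]))
            out[pid] = np.concatenate([embeddings[pid][:T], emotions[pid][:T]], axis=1)
        return out
    raise ValueError("source must be 'embeddings', 'emotion', or 'embeddings+emotion'")
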