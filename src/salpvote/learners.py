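"""The five base classifiers and their training-accuracy ranking.

SVM, random forest and AdaBoost come from scikit-learn, gradient-boosted
trees from xgboost, and the extreme learning machine (a single-hidden-layer
network with random untrained input weights and ridge-regularized
least-squares output weights) is implemented here as a scikit-learn
compatible estimator. "Accuracy during training" is read as stratified
cross-validated accuracy on the training split (resubstitution accuracy
would trivially favour interpolating learners); a ``resubstitution`` flag
restores the literal reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import ConfigError, StratificationError

__all__ = [
    "LEARNER_IDS",
    "ELMClassifier",
    "train_elm",
    "LearnerFit",
    "LearnerRanking",
    "build_learner",
    "train_base_learners",
    "rank_learners",
]

#: Fixed id order; also the final tie-break in the ranking.
LEARNER_IDS = ("SVM", "RF", "ELM", "AdaBoost", "XGBoost")


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Extreme learning machine: random hidden layer, least-squares read-out.

    Input weights and biases are drawn uniform[-1, 1] from the seed and never
    trained; the hidden layer is sigmoid(X W + b); the output weights solve
    the ridge-regularized least squares of the hidden layer against one-hot
    labels. Prediction is the argmax of the read-out.
    """

    def __init__(self, n_hidden: int = 256, ridge: float = 1e-3, random_state: int = 0):
        self.n_hidden = n_hidden
        self.ridge = ridge
        self.random_state = random_state

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def _hidden(self, X):
        return self._sigmoid(X @ self.input_weights_ + self.biases_)

    def fit(self, X, y):
        if self.n_hidden < 1:
            raise ConfigError("n_hidden must be >= 1")
        if self.ridge < 0:
            raise ConfigError("ridge must be >= 0")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        d = X.shape[1]
        self.input_weights_ = rng.uniform(-1, 1, size=(d, self.n_hidden))
        self.biases_ = rng.uniform(-1, 1, size=self.n_hidden)
        H = self._hidden(X)
        Y = np.eye(len(self.classes_))[codes]
        if self.ridge > 0:
            A = H.T @ H + self.ridge * np.eye(self.n_hidden)
            self.output_weights_ = np.linalg.solve(A, H.T @ Y)
        else:
            self.output_weights_, *_ = np.linalg.lstsq(H, Y, rcond=None)
        return self

    def decision_function(self, X):
        return self._hidden(np.asarray(X, dtype=float)) @ self.output_weights_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def predict_proba(self, X):
        scores = self.decision_function(X)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)


def train_elm(X, y, n_hidden: int = 256, ridge: float = 1e-3, seed: int = 0) -> ELMClassifier:
    """Fit an :class:`ELMClassifier` (functional convenience wrapper)."""
    return ELMClassifier(n_hidden=n_hidden, ridge=ridge, random_state=seed).fit(X, y)


def build_learner(learner_id: str, seed: int = 0, hyperparameters: dict = None):
    """Construct one of the five base learners with its default hyperparameters."""
    hp = dict(hyperparameters or {})
    if learner_id == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed, **hp)
    if learner_id == "RF":
        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1, **hp)
    if learner_id == "ELM":
        return ELMClassifier(random_state=seed, **hp)
    if learner_id == "AdaBoost":
        return AdaBoostClassifier(n_estimators=200, random_state=seed, **hp)
    if learner_id == "XGBoost":
        return XGBClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbosity=0, **hp,
        )
    raise ConfigError(f"unknown learner id {learner_id!r}; expected one of {LEARNER_IDS}")


@dataclass
class LearnerFit:
    learner_id: str
    model: object
    cv_accuracy: float
    macro_f1: float


@dataclass
class LearnerRanking:
    """Learner ids ordered by descending training-phase accuracy."""

    ordered_ids: list
    accuracies: dict
    top_k: int = 3

    @property
    def top_ids(self) -> list:
        return self.ordered_ids[: self.top_k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "learner_id": self.ordered_ids,
                "cv_accuracy": [self.accuracies[i] for i in self.ordered_ids],
                "rank": range(1, len(self.ordered_ids) + 1),
            }
        )


def train_base_learners(
    X,
    y,
    seed: int = 0,
    hyperparameters: dict = None,
    cv_folds: int = 5,
    resubstitution: bool = False,
) -> dict:
    """Fit all five learners and record their training-split accuracy.

    Labels must be encoded as contiguous integers (xgboost requires it).
    Returns ``{learner_id: LearnerFit}``; a failing learner aborts with its id.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise StratificationError("need at least 2 classes")
    hyperparameters = hyperparameters or {}
    folds = min(cv_folds, int(np.bincount(y).min()))
    if folds < 2 and not resubstitution:
        raise StratificationError("smallest class too small for cross-validation")
    fits = {}
    for learner_id in LEARNER_IDS:
        try:
            model = build_learner(learner_id, seed=seed, hyperparameters=hyperparameters.get(learner_id))
            if resubstitution:
                model.fit(X, y)
                pred = model.predict(X)
            else:
                skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
                pred = cross_val_predict(model, X, y, cv=skf)
                model.fit(X, y)
            fits[learner_id] = LearnerFit(
                learner_id=learner_id,
                model=model,
                cv_accuracy=float(accuracy_score(y, pred)),
                macro_f1=float(f1_score(y, pred, average="macro")),
            )
        except Exception as exc:  # noqa: BLE001 - abort naming the learner
            raise RuntimeError(f"base learner {learner_id} failed: {exc}") from exc
    return fits


def rank_learners(accuracies: dict, k: int = 3, macro_f1: dict = None) -> LearnerRanking:
    """Order learners by descending accuracy; ties by macro-F1, then fixed id order."""
    if k > len(accuracies):
        raise ConfigError("k exceeds the number of learners")
    macro_f1 = macro_f1 or {}
    fixed = {lid: i for i, lid in enumerate(LEARNER_IDS)}
    ordered = sorted(
        accuracies,
        key=lambda lid: (-accuracies[lid], -macro_f1.get(lid, 0.0), fixed.get(lid, len(fixed))),
    )
    return LearnerRanking(ordered_ids=ordered, accuracies=dict(accuracies), top_k=k)
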