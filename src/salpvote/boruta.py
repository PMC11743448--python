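"""All-relevant gene filtering with shadow features and a random forest.

Each round, every candidate gene receives a shadow copy whose values are an
independent row permutation of the original, destroying any association with
the class while preserving the marginal distribution. A random forest is fit
on the combined matrix and the per-column mean-decrease-in-impurity
importance is computed; the round's threshold is the maximum importance among
the shadows. A gene scores a "hit" when its importance exceeds the threshold.
After every round a one-sided binomial test against p = 0.5 confirms genes
with significantly many hits and rejects genes with significantly few;
rejected genes (and their shadows) leave the forest. Genes still tentative at
the iteration cap are resolved by comparing their median importance to the
median of the per-round thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from .dataset_io import ExpressionDataset
from .errors import ConfigError

__all__ = [
    "BorutaConfig",
    "BorutaResult",
    "make_shadow_features",
    "forest_importance",
    "shadow_threshold",
    "run_boruta",
]

CONFIRMED, REJECTED, TENTATIVE = "confirmed", "rejected", "tentative"


@dataclass
class BorutaConfig:
    n_trees: int = 300
    max_iterations: int = 50
    significance: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 10:
            raise ConfigError("n_trees must be >= 10")
        if self.max_iterations < 10:
            raise ConfigError("max_iterations must be >= 10")
        if not 0 < self.significance < 1:
            raise ConfigError("significance must be in (0, 1)")


@dataclass
class BorutaResult:
    """Per-gene status with the full importance and threshold history.

    ``importance_history`` has one row per iteration and 2p columns (original
    genes then shadows); columns of genes absent from a round are NaN.
    ``thresholds[t]`` is the maximum shadow importance at iteration t.
    """

    status: dict
    importance_history: np.ndarray
    thresholds: list
    selected_ids: list
    hits: dict = field(default_factory=dict)
    n_iterations: int = 0
    resolved_from_tentative: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "status": self.status,
            "selected_ids": self.selected_ids,
            "thresholds": list(map(float, self.thresholds)),
            "hits": self.hits,
            "n_iterations": self.n_iterations,
            "resolved_from_tentative": self.resolved_from_tentative,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    def write_selected(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.selected_ids) + ("\n" if self.selected_ids else ""))


def make_shadow_features(X: np.ndarray, rng: np.random.Generator):
    """Append an independently row-permuted copy of every column.

    Returns ``(X_integrated, is_shadow)`` where column ``j + p`` of the
    integrated matrix is a permutation of column ``j`` and ``is_shadow`` flags
    the appended columns.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("X must be non-empty")
    n, p = X.shape
    shadows = np.empty_like(X)
    for j in range(p):
        shadows[:, j] = X[rng.permutation(n), j]
    integrated = np.hstack([X, shadows])
    is_shadow = np.zeros(2 * p, dtype=bool)
    is_shadow[p:] = True
    return integrated, is_shadow


def forest_importance(X_integrated: np.ndarray, y: np.ndarray, config: BorutaConfig) -> np.ndarray:
    """Mean-decrease-in-impurity importance per column from a random forest."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
    )
    forest.fit(X_integrated, y)
    return forest.feature_importances_


def shadow_threshold(shadow_scores) -> float:
    """The round threshold: the maximum importance among the shadow features."""
    shadow_scores = np.asarray(shadow_scores, dtype=float)
    if shadow_scores.size == 0:
        raise ValueError("need at least one shadow score")
    return float(shadow_scores.max())


def run_boruta(dataset: ExpressionDataset, config: BorutaConfig = None) -> BorutaResult:
    """Iterative all-relevant filtering of ``dataset``'s genes.

    Statuses partition the gene set into confirmed / rejected (no gene is
    left tentative: leftovers at the cap are resolved by the median rule and
    recorded in ``resolved_from_tentative``).
    """
    import dataclasses

    config = config or BorutaConfig()
    config.validate()
    dataset.require_min_class_size(2)
    X = dataset.values
    y = dataset.encoded_labels
    n, p = X.shape
    rng = np.random.default_rng(config.seed)

    status = np.full(p, TENTATIVE, dtype=object)
    hits = np.zeros(p, dtype=int)
    trials = np.zeros(p, dtype=int)
    history = []
    thresholds = []

    for t in range(config.max_iterations):
        active = status != REJECTED  # confirmed genes stay in the competition
        idx = np.flatnonzero(active)
        integrated, is_shadow = make_shadow_features(X[:, idx], rng)
        round_cfg = dataclasses.replace(config, seed=int(rng.integers(2**31)))
        imp = forest_importance(integrated, y, round_cfg)
        orig_imp = imp[~is_shadow]
        ith = shadow_threshold(imp[is_shadow])
        thresholds.append(ith)

        row = np.full(2 * p, np.nan)
        row[idx] = orig_imp
        row[p + idx] = imp[is_shadow]
        history.append(row)

        hit = orig_imp > ith
        hits[idx] += hit.astype(int)
        trials[idx] += 1

        for j in np.flatnonzero(status == TENTATIVE):
            if binomtest(hits[j], trials[j], 0.5, alternative="greater").pvalue < config.significance:
                status[j] = CONFIRMED
            elif binomtest(hits[j], trials[j], 0.5, alternative="less").pvalue < config.significance:
                status[j] = REJECTED
        if not np.any(status == TENTATIVE):
            break

    history = np.asarray(history)
    resolved = []
    leftover = np.flatnonzero(status == TENTATIVE)
    if leftover.size:
        median_threshold = float(np.median(thresholds))
        for j in leftover:
            med = np.nanmedian(history[:, j])
            status[j] = CONFIRMED if med > median_threshold else REJECTED
            resolved.append(dataset.gene_ids[j])

    status_map = {g: s for g, s in zip(dataset.gene_ids, status)}
    selected = [g for g, s in status_map.items() if s == CONFIRMED]
    return BorutaResult(
        status=status_map,
        importance_history=history,
        thresholds=thresholds,
        selected_ids=selected,
        hits={g: int(h) for g, h in zip(dataset.gene_ids, hits)},
        n_iterations=len(thresholds),
        resolved_from_tentative=resolved,
    )
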