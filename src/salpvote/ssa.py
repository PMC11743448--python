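"""Salp-swarm wrapper optimization of a gene subset.

A swarm of salps moves in a continuous box [lb, ub]^d; a position is decoded
into a 0/1 gene mask by thresholding each coordinate at 0 (the midpoint of
the sigmoid transfer function), and a mask's fitness is the stratified k-fold
cross-validated accuracy of a wrapped classifier on the masked training data.
Internally the objective 1 - ACC_avg is minimized.

Every iteration applies two phases to each salp's position and accepts the
combined candidate only on strict improvement:

* exploration -- a social term pulling toward the swarm mean, a personal term
  pulling toward the salp's best position, and a randomized exploration term,
  combined with step size gamma1 and damping gamma2;
* exploitation -- leader-follower dynamics: the leader takes a random drift
  scaled by the box, each follower moves to the midpoint of itself and its
  predecessor (pre-step positions).

Positions are clipped to the box after every phase, so the best-fitness trace
is non-decreasing by construction of the acceptance rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .errors import ConfigError, StratificationError

__all__ = [
    "SSAConfig",
    "SwarmState",
    "SSAResult",
    "binarize",
    "cv_fitness",
    "exploration_step",
    "exploitation_step",
    "accept_and_update",
    "run_ssa",
]


@dataclass
class SSAConfig:
    max_iterations: int = 100
    num_salps: int = 30
    lb: float = -10.0
    ub: float = 10.0
    gamma1: float = 1.0
    gamma2: float = 0.8
    cv_folds: int = 5
    evaluator: str = "1nn"
    seed: int = 0
    canonical_leader: bool = False  # food-source leader update instead of the literal drift
    exploration: bool = True
    exploitation: bool = True

    def validate(self) -> None:
        if self.lb >= self.ub:
            raise ConfigError("lb must be < ub")
        if self.max_iterations < 1 or self.num_salps < 2 or self.cv_folds < 2:
            raise ConfigError("max_iterations >= 1, num_salps >= 2, cv_folds >= 2 required")


@dataclass
class SwarmState:
    """Positions, personal bests and fitness bookkeeping for the swarm."""

    positions: np.ndarray          # num_salps x d, within [lb, ub]
    personal_best: np.ndarray      # per-salp best position
    objectives: np.ndarray         # per-salp 1 - ACC_avg at the current position
    best_position: np.ndarray
    best_fitness: float            # ACC_avg of the global best
    trace: list = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return 1.0 - self.objectives


@dataclass
class SSAResult:
    mask: np.ndarray               # boolean over the candidate genes
    fitness: float                 # best cross-validated accuracy
    trace: list                    # best fitness per iteration (non-decreasing)
    n_evaluations: int
    seed: int

    def to_json(self, path, gene_ids=None, config: SSAConfig = None) -> None:
        payload = {
            "selected": (
                [g for g, m in zip(gene_ids, self.mask) if m]
                if gene_ids is not None
                else np.flatnonzero(self.mask).tolist()
            ),
            "fitness": self.fitness,
            "trace": list(map(float, self.trace)),
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "config": vars(config) if config else None,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def binarize(position: np.ndarray) -> np.ndarray:
    """Gene j is included iff sigmoid(position_j) > 0.5, i.e. position_j > 0.

    An all-excluded position falls back to the single gene with the largest
    coordinate so the mask is never empty.
    """
    position = np.asarray(position, dtype=float)
    mask = position > 0
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


def _build_evaluator(name: str):
    if name == "1nn":
        return lambda: KNeighborsClassifier(n_neighbors=1)
    if callable(name):
        return name
    raise ConfigError(f"unknown evaluator {name!r}")


class _FitnessCache:
    """Memoized mask -> CV accuracy on fixed, seeded stratified folds."""

    def __init__(self, X: np.ndarray, y: np.ndarray, config: SSAConfig):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        smallest = np.bincount(self.y).min()
        if smallest < config.cv_folds:
            raise StratificationError(
                f"smallest class ({smallest}) cannot fill {config.cv_folds} stratified folds"
            )
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        self.folds = list(skf.split(self.X, self.y))
        self.make_model = _build_evaluator(config.evaluator)
        self.memo = {}
        self.n_evaluations = 0

    def accuracy(self, mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=bool).tobytes()
        if key in self.memo:
            return self.memo[key]
        Xm = self.X[:, mask]
        correct = 0
        for tr, te in self.folds:
            model = self.make_model().fit(Xm[tr], self.y[tr])
            correct += int(np.sum(model.predict(Xm[te]) == self.y[te]))
        acc = correct / len(self.y)
        self.memo[key] = acc
        self.n_evaluations += 1
        return acc


def cv_fitness(mask: np.ndarray, X: np.ndarray, y: np.ndarray, config: SSAConfig = None) -> float:
    """ACC_avg: mean stratified k-fold CV accuracy of the wrapped classifier."""
    config = config or SSAConfig()
    config.validate()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must select at least one gene")
    return _FitnessCache(X, y, config).accuracy(mask)


def exploration_step(positions, personal_best, accuracies, config: SSAConfig, rng) -> np.ndarray:
    """Candidate positions from the social / personal / exploration terms.

    For salp i with fitness F_i (accuracy): S_i = F_i * mean_j(X_j - X_i),
    P_i = F_i * (Xb_i - X_i), E_i = kappa * R * (Xb_i - X_i) with kappa, R
    fresh uniform[0,1] draws per component; the candidate is
    X_i + gamma1 * S_i + gamma2 * (P_i + E_i), clipped to the box.
    """
    positions = np.asarray(positions, dtype=float)
    n, d = positions.shape
    acc = np.asarray(accuracies, dtype=float)[:, None]
    if n > 1:
        social = acc * (positions.sum(axis=0) - n * positions) / (n - 1)
    else:
        social = np.zeros_like(positions)
    to_best = np.asarray(personal_best, dtype=float) - positions
    personal = acc * to_best
    kappa = rng.uniform(0, 1, size=(n, d))
    r_draw = rng.uniform(0, 1, size=(n, d))
    explore = kappa * r_draw * to_best
    candidate = positions + config.gamma1 * social + config.gamma2 * (personal + explore)
    return np.clip(candidate, config.lb, config.ub)


def exploitation_step(positions, config: SSAConfig, rng, best_position=None) -> np.ndarray:
    """Leader drift plus follower chain-averaging, using pre-step positions.

    The leader (salp 0) moves by c1 * ((ub - lb) * c2 + lb) per component
    (or, with ``canonical_leader``, jumps around the global best position);
    follower i moves to the midpoint of its own and its predecessor's
    pre-step position.
    """
    old = np.asarray(positions, dtype=float)
    n, d = old.shape
    if n < 2:
        raise ConfigError("exploitation requires num_salps >= 2")
    new = old.copy()
    c1 = rng.uniform(0, 1, size=d)
    c2 = rng.uniform(0, 1, size=d)
    span = config.ub - config.lb
    if config.canonical_leader and best_position is not None:
        sign = np.where(rng.uniform(0, 1, size=d) < 0.5, 1.0, -1.0)
        new[0] = best_position + sign * c1 * (span * c2 + config.lb)
    else:
        new[0] = old[0] + c1 * (span * c2 + config.lb)
    new[1:] = 0.5 * (old[1:] + old[:-1])
    return np.clip(new, config.lb, config.ub)


def accept_and_update(state: SwarmState, candidates: np.ndarray, cache: _FitnessCache) -> SwarmState:
    """Greedy acceptance: keep a candidate only if its objective strictly drops."""
    for i, cand in enumerate(np.asarray(candidates, dtype=float)):
        obj = 1.0 - cache.accuracy(binarize(cand))
        if obj < state.objectives[i]:
            state.positions[i] = cand
            state.objectives[i] = obj
            state.personal_best[i] = cand
            if 1.0 - obj > state.best_fitness:
                state.best_fitness = 1.0 - obj
                state.best_position = cand.copy()
    return state


def run_ssa(X: np.ndarray, y: np.ndarray, config: SSAConfig = None) -> SSAResult:
    """Optimize a gene mask over the candidate genes of ``X``.

    Positions are initialized uniformly in the box; each iteration applies
    exploration then exploitation to produce candidates and accepts per salp
    on strict improvement. Returns the global-best mask, its cross-validated
    accuracy, and the per-iteration best-fitness trace.
    """
    config = config or SSAConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ConfigError("X must be samples x genes with at least one gene")
    rng = np.random.default_rng(config.seed)
    cache = _FitnessCache(X, y, config)
    d = X.shape[1]

    positions = rng.uniform(config.lb, config.ub, size=(config.num_salps, d))
    objectives = np.array([1.0 - cache.accuracy(binarize(p)) for p in positions])
    best_i = int(np.argmin(objectives))
    state = SwarmState(
        positions=positions,
        personal_best=positions.copy(),
        objectives=objectives,
        best_position=positions[best_i].copy(),
        best_fitness=1.0 - objectives[best_i],
    )

    for _ in range(config.max_iterations):
        candidates = state.positions
        if config.exploration:
            candidates = exploration_step(
                candidates, state.personal_best, state.accuracies, config, rng
            )
        if config.exploitation:
            candidates = exploitation_step(candidates, config, rng, state.best_position)
        state = accept_and_update(state, candidates, cache)
        assert np.all(state.positions >= config.lb) and np.all(state.positions <= config.ub)
        state.trace.append(state.best_fitness)

    return SSAResult(
        mask=binarize(state.best_position),
        fitness=state.best_fitness,
        trace=state.trace,
        n_evaluations=cache.n_evaluations,
        seed=config.seed,
    )
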