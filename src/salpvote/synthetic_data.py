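"""Seeded synthetic expression datasets with planted structure.

Emulates the shape of small-n / large-p tumour expression studies:
60-90 samples, thousands of genes, 3-4 imbalanced classes. Three gene kinds
are planted so every pipeline stage has a known ground truth:

* informative genes -- baseline Gaussian noise plus a class-specific mean
  shift of ``effect_size * noise_sd`` (class ``c`` is shifted by
  ``c * effect_size * noise_sd``, so adjacent classes differ by one effect);
* redundant genes -- a randomly chosen informative gene plus zero-mean
  Gaussian perturbation (SD ``redundancy_noise_sd``);
* noise genes -- pure baseline noise.

Class sizes follow largest-remainder rounding of the requested proportions,
so fixture dimensions are exact and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset_io import ExpressionDataset, _largest_remainder
from .errors import ConfigError

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset", "write_ground_truth"]

#: Default study conditions: 80 samples, 2000 genes, three imbalanced classes,
#: 10 informative genes at effect size 3, 40 correlated redundant copies.
DEFAULT_PROPORTIONS = (0.5, 0.3, 0.2)


@dataclass
class SyntheticSpec:
    n_samples: int = 80
    n_genes: int = 2000
    class_proportions: tuple = DEFAULT_PROPORTIONS
    n_informative: int = 10
    effect_size: float = 3.0
    n_redundant: int = 40
    redundancy_noise_sd: float = 0.25
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_informative) < 1:
            raise ConfigError("counts must be positive")
        if self.n_redundant < 0 or self.n_informative + self.n_redundant > self.n_genes:
            raise ConfigError("n_informative + n_redundant must be <= n_genes")
        if not 3 <= len(self.class_proportions) <= 4:
            raise ConfigError("3-4 classes expected")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigError("class_proportions must sum to 1")
        if self.noise_sd <= 0 or self.redundancy_noise_sd < 0 or self.effect_size < 0:
            raise ConfigError("noise_sd must be > 0; effect/perturbation SDs non-negative")


@dataclass
class GroundTruth:
    """Partition of gene identifiers into planted roles."""

    informative_ids: list
    redundant_ids: dict  # redundant gene id -> source informative gene id
    noise_ids: list
    seed: int = 0
    spec: dict = field(default_factory=dict)


def generate_dataset(spec: SyntheticSpec):
    """Generate a seeded ``(ExpressionDataset, GroundTruth)`` pair."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_genes

    counts = _largest_remainder(
        np.asarray(spec.class_proportions) * n, n
    )
    labels = np.repeat(np.arange(len(counts)), counts)

    values = rng.normal(0.0, spec.noise_sd, size=(n, p))

    roles = rng.permutation(p)
    informative = roles[: spec.n_informative]
    redundant = roles[spec.n_informative : spec.n_informative + spec.n_redundant]

    shift = spec.effect_size * spec.noise_sd
    values[:, informative] += (labels * shift)[:, None]

    gene_ids = [f"g{j:05d}" for j in range(p)]
    redundant_map = {}
    for j in redundant:
        src = informative[rng.integers(len(informative))]
        values[:, j] = values[:, src] + rng.normal(0.0, spec.redundancy_noise_sd, size=n)
        redundant_map[gene_ids[j]] = gene_ids[src]

    planted = set(informative) | set(redundant)
    truth = GroundTruth(
        informative_ids=[gene_ids[j] for j in sorted(informative)],
        redundant_ids=redundant_map,
        noise_ids=[gene_ids[j] for j in range(p) if j not in planted],
        seed=spec.seed,
        spec=asdict(spec),
    )
    dataset = ExpressionDataset(
        values=values,
        gene_ids=gene_ids,
        sample_ids=[f"s{i:04d}" for i in range(n)],
        labels=labels,
    )
    return dataset, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "informative_ids": truth.informative_ids,
        "redundant_ids": truth.redundant_ids,
        "noise_ids": truth.noise_ids,
        "seed": truth.seed,
        "spec": truth.spec,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
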