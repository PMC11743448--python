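"""Expression-table I/O, normalization, label encoding and stratified splitting.

The in-memory container is :class:`ExpressionDataset`: a samples x genes
matrix of expression intensities with one categorical class label per sample.
Tables are read from delimited text (genes as columns, one designated label
column). Normalization is per-gene min-max scaling fitted on the training
split only; splitting is stratified with largest-remainder allocation so that
per-class training proportions differ from the global ratio by less than one
sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError, StratificationError

__all__ = [
    "ExpressionDataset",
    "SplitResult",
    "load_expression_table",
    "minmax_normalize",
    "stratified_split",
    "write_expression_csv",
    "write_split_membership",
]


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with per-sample class labels.

    Parameters
    ----------
    values
        Float matrix, one row per sample, one column per gene.
    gene_ids
        Ordered unique gene identifiers (column names).
    sample_ids
        Ordered unique sample identifiers (row names).
    labels
        Per-sample class label, any hashable type.
    class_names
        Ordered distinct labels. Defaults to first-appearance order of
        ``labels``; this order defines the integer encoding.
    """

    values: np.ndarray
    gene_ids: list
    sample_ids: list
    labels: np.ndarray
    class_names: list = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise DataFormatError("values must be a 2-D samples x genes matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise DataFormatError(
                f"row count {n} does not match sample_ids/labels lengths "
                f"({len(self.sample_ids)}/{len(self.labels)})"
            )
        if len(self.gene_ids) != p:
            raise DataFormatError(
                f"column count {p} does not match gene_ids length {len(self.gene_ids)}"
            )
        if len(set(self.gene_ids)) != p:
            raise DataFormatError("gene identifiers are not unique")
        if len(set(self.sample_ids)) != n:
            raise DataFormatError("sample identifiers are not unique")
        if self.class_names is None:
            self.class_names = list(pd.unique(self.labels))
        else:
            self.class_names = list(self.class_names)

    # -- bookkeeping -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def encoded_labels(self) -> np.ndarray:
        """Labels as contiguous integers in ``class_names`` order."""
        index = {c: i for i, c in enumerate(self.class_names)}
        return np.array([index[v] for v in self.labels], dtype=int)

    def class_counts(self) -> dict:
        return {c: int(np.sum(self.labels == c)) for c in self.class_names}

    def require_min_class_size(self, k: int = 2) -> None:
        """Raise if any class has fewer than ``k`` samples or < 2 classes exist."""
        counts = self.class_counts()
        if len(counts) < 2:
            raise StratificationError("dataset has fewer than 2 classes")
        small = {c: m for c, m in counts.items() if m < k}
        if small:
            raise StratificationError(f"classes with fewer than {k} samples: {small}")

    def subset_samples(self, indices) -> "ExpressionDataset":
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            values=self.values[indices],
            gene_ids=self.gene_ids,
            sample_ids=[self.sample_ids[i] for i in indices],
            labels=self.labels[indices],
            class_names=self.class_names,
        )

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise DataFormatError(f"unknown gene identifiers: {missing[:5]}")
        cols = [index[g] for g in gene_ids]
        return ExpressionDataset(
            values=self.values[:, cols],
            gene_ids=list(gene_ids),
            sample_ids=self.sample_ids,
            labels=self.labels,
            class_names=self.class_names,
        )

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self, label_column: str = "class") -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        frame[label_column] = self.labels
        return frame


@dataclass
class SplitResult:
    """A stratified train/test partition of an :class:`ExpressionDataset`."""

    train: ExpressionDataset
    test: ExpressionDataset
    ratio: float
    seed: int


def load_expression_table(path, label_column: str = "class", delimiter: str = ",") -> ExpressionDataset:
    """Read a delimited expression table (genes as columns, one label column).

    Raises
    ------
    DataFormatError
        Missing label column, duplicate gene identifiers, non-numeric or
        missing cells (the message names the offending sample and gene).
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split(delimiter)
    if label_column not in header:
        raise DataFormatError(f"label column {label_column!r} not found in header")
    gene_cols = [c for c in header if c != label_column]
    dupes = {c for c in gene_cols if gene_cols.count(c) > 1}
    if dupes or header.count(label_column) > 1:
        raise DataFormatError(f"duplicate column names: {sorted(dupes) or [label_column]}")

    frame = pd.read_csv(path, sep=delimiter)
    frame.columns = header  # undo pandas de-duplication mangling (none expected here)
    labels = frame[label_column].to_numpy()
    genes = frame[gene_cols]
    numeric = genes.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"non-numeric or missing value at row {i} (sample index), column {gene_cols[j]!r}"
        )
    dataset = ExpressionDataset(
        values=numeric.to_numpy(dtype=float),
        gene_ids=gene_cols,
        sample_ids=[str(s) for s in frame.index],
        labels=labels,
    )
    dataset.require_min_class_size(1)  # >= 2 classes; size checks happen at split time
    return dataset


def write_expression_csv(dataset: ExpressionDataset, path, label_column: str = "class") -> None:
    dataset.to_frame(label_column).to_csv(path, index=False)


def minmax_normalize(train: ExpressionDataset, test: ExpressionDataset = None):
    """Scale each gene to [0, 1] using training-split statistics only.

    Each train gene is mapped by (x - min) / (max - min). A constant train
    gene maps to 0 everywhere (divisor replaced by 1, keeping the transform
    affine). Test values are transformed with the train statistics and are
    deliberately not clipped, so they may fall outside [0, 1].

    Returns
    -------
    (train_norm, test_norm, (mins, maxs))
        ``test_norm`` is None when ``test`` is None.
    """
    if train.n_samples == 0:
        raise DataFormatError("cannot normalize an empty training set")
    mins = train.values.min(axis=0)
    maxs = train.values.max(axis=0)
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    train_norm = train.with_values((train.values - mins) / safe)
    test_norm = None
    if test is not None:
        test_norm = test.with_values((test.values - mins) / safe)
    return train_norm, test_norm, (mins, maxs)


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total`` by the largest-remainder rule."""
    floors = np.floor(quotas).astype(int)
    remainder = int(total - floors.sum())
    if remainder > 0:
        frac = quotas - floors
        # ties broken toward earlier (larger-first ordering is stable on -frac)
        order = np.argsort(-frac, kind="stable")
        floors[order[:remainder]] += 1
    return floors


def stratified_split(dataset: ExpressionDataset, ratio: float = 0.85, seed: int = 0) -> SplitResult:
    """Stratified train/test split with |train| = floor(ratio * n).

    Per-class train counts follow largest-remainder allocation of the class
    quotas ratio * n_c, so every class is represented in train and per-class
    proportions differ from the global ratio by less than one sample.
    Membership is reproducible for a fixed seed.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    counts = dataset.class_counts()
    singles = {c: m for c, m in counts.items() if m < 2}
    if singles:
        raise StratificationError(f"cannot stratify classes with one sample: {singles}")
    n = dataset.n_samples
    n_train = int(np.floor(ratio * n))
    class_sizes = np.array([counts[c] for c in dataset.class_names], dtype=float)
    quotas = ratio * class_sizes
    alloc = _largest_remainder(quotas, n_train)
    # every class must appear in train; borrow from the largest allocation if needed
    while (alloc == 0).any():
        alloc[np.argmin(alloc)] += 1
        alloc[np.argmax(alloc)] -= 1
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c, k in zip(dataset.class_names, alloc):
        members = np.flatnonzero(dataset.labels == c)
        members = members[rng.permutation(len(members))]
        train_idx.extend(members[:k])
        test_idx.extend(members[k:])
    train_idx = sorted(train_idx)
    test_idx = sorted(test_idx)
    return SplitResult(
        train=dataset.subset_samples(train_idx),
        test=dataset.subset_samples(test_idx),
        ratio=ratio,
        seed=seed,
    )


def write_split_membership(split: SplitResult, path) -> None:
    """Two-column sample_id,partition CSV recording the split."""
    rows = [(s, "train") for s in split.train.sample_ids]
    rows += [(s, "test") for s in split.test.sample_ids]
    pd.DataFrame(rows, columns=["sample_id", "partition"]).to_csv(path, index=False)
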