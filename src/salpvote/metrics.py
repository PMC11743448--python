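"""Classification metric battery with exact binomial confidence intervals.

All metrics are defined on one-vs-rest confusion counts per class and
macro-averaged (accuracy and misclassification rate are overall quantities).
The identities ACC + MCR = 1, FNR = 1 - REC and FPR = 1 - SPE hold exactly on
the raw (unrounded) values. Confidence intervals are Clopper-Pearson exact
binomial intervals from Beta quantiles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataFormatError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "f_beta",
    "compute_metrics",
    "clopper_pearson",
    "macro_ovr_auc",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for every class.

    ``per_class[c] = (tp, fp, tn, fn)``; the four counts sum to the number of
    samples for every class.
    """

    per_class: dict
    n: int


def confusion_counts(y_true, y_pred, classes=None) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise DataFormatError("y_true and y_pred must have equal length")
    if classes is None:
        classes = list(pd.unique(np.concatenate([y_true, y_pred])))
    classes = [c.item() if hasattr(c, "item") else c for c in classes]  # JSON-safe keys
    known = set(classes)
    unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - known
    if unknown:
        raise DataFormatError(f"labels outside the class set: {sorted(map(str, unknown))}")
    n = len(y_true)
    per_class = {}
    for c in classes:
        t, p = y_true == c, y_pred == c
        tp = int(np.sum(t & p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        tn = n - tp - fp - fn
        per_class[c] = (tp, fp, tn, fn)
    return ConfusionCounts(per_class=per_class, n=n)


def f_beta(precision: float, recall: float, beta: float) -> float:
    """(1 + beta^2) P R / (beta^2 P + R); 0 by convention when P = R = 0."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def _safe_div(num, den):
    return num / den if den > 0 else None


def _per_class_metrics(tp, fp, tn, fn):
    pre = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    spe = _safe_div(tn, tn + fp)
    fnr = None if rec is None else 1.0 - rec
    fpr = None if spe is None else 1.0 - spe
    f1 = None if (pre is None or rec is None) else f_beta(pre, rec, 1.0)
    f2 = None if (pre is None or rec is None) else f_beta(pre, rec, 2.0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return {
        "PRE": pre, "REC": rec, "SPE": spe, "F1": f1, "F2": f2,
        "FNR": fnr, "FPR": fpr, "MCC": mcc,
    }


@dataclass
class MetricsReport:
    """Overall and macro-averaged classification metrics.

    ``ACC``/``MCR`` are overall; the rest are unweighted macro averages over
    classes present in the truth (classes with an undefined per-class value
    are excluded from that metric's average). ``ci`` maps metric name to a
    Clopper-Pearson interval computed at the evaluation-set size.
    """

    ACC: float
    MCR: float
    PRE: float
    REC: float
    SPE: float
    F1: float
    F2: float
    FNR: float
    FPR: float
    MCC: float
    n: int
    per_class: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    confidence: float = 0.95

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("ACC", "MCR", "PRE", "REC", "SPE", "F1", "F2", "FNR", "FPR", "MCC"):
            lo, hi = self.ci.get(name, (None, None))
            rows.append({"metric": name, "value": getattr(self, name), "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)


def compute_metrics(y_true, y_pred, classes=None, confidence: float = 0.95) -> MetricsReport:
    """Compute the full metric battery from hard predictions."""
    counts = confusion_counts(y_true, y_pred, classes)
    y_true = np.asarray(y_true)
    n = counts.n
    if n < 1:
        raise DataFormatError("need at least one sample")
    acc = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    present = [c for c in counts.per_class if np.any(y_true == c)]
    per_class = {c: _per_class_metrics(*counts.per_class[c]) for c in present}

    def macro(name):
        vals = [m[name] for m in per_class.values() if m[name] is not None]
        return float(np.mean(vals)) if vals else float("nan")

    report = MetricsReport(
        ACC=acc,
        MCR=1.0 - acc,
        PRE=macro("PRE"),
        REC=macro("REC"),
        SPE=macro("SPE"),
        F1=macro("F1"),
        F2=macro("F2"),
        FNR=macro("FNR"),
        FPR=macro("FPR"),
        MCC=macro("MCC"),
        n=n,
        per_class=per_class,
        confidence=confidence,
    )
    # proportion-type metrics get exact intervals at the evaluation-set size
    for name in ("ACC", "PRE", "REC", "SPE", "F1", "F2"):
        value = getattr(report, name)
        if np.isfinite(value):
            k = int(round(value * n))
            report.ci[name] = clopper_pearson(k, n, confidence)
    return report


def clopper_pearson(successes: int, n: int, confidence: float = 0.95):
    """Exact binomial confidence interval from Beta quantiles.

    Lower endpoint is 0 when ``successes == 0`` and the upper endpoint is 1
    when ``successes == n``.
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError("require 0 <= successes <= n and n >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def macro_ovr_auc(y_true, scores, classes=None) -> float:
    """Macro one-vs-rest AUC from per-class scores (ties get half credit).

    ``scores`` is a samples x classes array whose column order matches
    ``classes``. Classes absent from the truth (or present in every sample)
    are excluded with a warning.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = list(range(scores.shape[1]))
    if scores.shape != (len(y_true), len(classes)):
        raise DataFormatError("scores must be samples x classes")
    aucs = []
    for j, c in enumerate(classes):
        pos = y_true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {c!r} absent from one side of the truth; excluded from AUC")
            continue
        ranks = stats.rankdata(scores[:, j])  # average ranks: ties get half credit
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    if not aucs:
        raise DataFormatError("no class with both positives and negatives")
    return float(np.mean(aucs))
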