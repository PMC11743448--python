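"""Hard majority-voting ensemble of the top-ranked base learners.

Each of the three members predicts a label; the ensemble outputs the modal
label. With three voters and three or more classes a full three-way tie can
occur, in which case the top-ranked member's prediction is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError

__all__ = ["EnsembleModel", "majority_vote", "predict_ensemble"]


@dataclass
class EnsembleModel:
    """Exactly three trained learners in ranking order plus the gene mask."""

    members: list          # [(learner_id, fitted model)] best-first
    feature_mask: np.ndarray  # boolean over the training gene set
    gene_ids: list = None     # gene ids of the training gene set, for alignment
    label_mapping: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.members) != 3:
            raise DataFormatError("an ensemble has exactly 3 members")
        self.feature_mask = np.asarray(self.feature_mask, dtype=bool)
        if not self.feature_mask.any():
            raise DataFormatError("feature mask must select at least one gene")


def majority_vote(per_member_predictions, ranking_order=(0, 1, 2)) -> np.ndarray:
    """Per-sample modal label of exactly 3 prediction vectors.

    ``ranking_order`` lists member indices best-first; a three-way tie yields
    the top-ranked member's prediction.
    """
    preds = [np.asarray(p) for p in per_member_predictions]
    if len(preds) != 3:
        raise DataFormatError("majority voting expects exactly 3 members")
    n = len(preds[0])
    if any(len(p) != n for p in preds):
        raise DataFormatError("prediction vectors must have equal length")
    top, second, third = (preds[i] for i in ranking_order)
    # if the two lower-ranked members agree against the leader, they win;
    # otherwise the leader's label is modal (>=2 votes) or it is a 3-way tie.
    out = np.where((second == third) & (second != top), second, top)
    return out


def predict_ensemble(model: EnsembleModel, X, gene_ids=None) -> np.ndarray:
    """Apply the gene mask, collect member predictions, and vote.

    ``X`` must carry the training gene set; if ``gene_ids`` is given the
    columns are aligned to the training order first and missing genes raise.
    """
    X = np.asarray(X, dtype=float)
    if gene_ids is not None and model.gene_ids is not None:
        index = {g: j for j, g in enumerate(gene_ids)}
        missing = [g for g in model.gene_ids if g not in index]
        if missing:
            raise DataFormatError(f"input is missing training genes: {missing[:5]}")
        X = X[:, [index[g] for g in model.gene_ids]]
    if X.shape[1] != len(model.feature_mask):
        raise DataFormatError(
            f"expected {len(model.feature_mask)} genes, got {X.shape[1]}"
        )
    Xm = X[:, model.feature_mask]
    votes = [m.predict(Xm) for _, m in model.members]
    return majority_vote(votes)


def votes_frame(model: EnsembleModel, X, sample_ids, gene_ids=None) -> pd.DataFrame:
    """Per-sample final prediction plus each member's vote, for export."""
    X = np.asarray(X, dtype=float)
    if gene_ids is not None and model.gene_ids is not None:
        index = {g: j for j, g in enumerate(gene_ids)}
        X = X[:, [index[g] for g in model.gene_ids]]
    Xm = X[:, model.feature_mask]
    votes = {lid: m.predict(Xm) for lid, m in model.members}
    final = majority_vote(list(votes.values()))
    frame = pd.DataFrame({"sample_id": sample_ids, "predicted_label": final})
    for lid, v in votes.items():
        frame[f"vote_{lid}"] = v
    return frame
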