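"""Permutation feature importance of the trained pixel classifier.

A feature matters if destroying its relationship with the other features
and the labels degrades the model's output.  Here each feature column of
the test set is shuffled (across the whole test set, ignoring cell
boundaries by default) and the mean absolute error between the new and
original softmax probability vectors — averaged over records and classes —
quantifies the disturbance.  Averaging over many shuffle rounds and
normalising across features so the importances sum to 1 gives a model-
agnostic importance ranking on probabilities rather than hard labels, so
small but systematic shifts register too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import TrainedModel
from .mapbuild import FEATURES

__all__ = ["ImportanceResult", "permutation_importance"]


@dataclass
class ImportanceResult:
    """Per-feature permutation importance.

    ``mae`` is the mean (over rounds) of the per-round MAE; ``traces`` the
    (rounds, n_features) per-round values; ``normalized`` sums to 1.
    """

    features: tuple[str, ...]
    mae: np.ndarray
    traces: np.ndarray
    normalized: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.features, "mae": self.mae, "importance": self.normalized}
        )


def permutation_importance(
    model: TrainedModel,
    records: pd.DataFrame,
    rounds: int = 20000,
    seed: int = 0,
    features: tuple[str, ...] = FEATURES,
    per_cell: bool = False,
) -> ImportanceResult:
    """Shuffle each feature ``rounds`` times and measure the prediction MAE.

    ``records`` must be normalized exactly as the model was trained.  With
    ``per_cell`` the permutation happens within each cell (requires a
    ``cell_id`` column) instead of across the full test set.  The default
    round count is sized for production runs; a few hundred rounds already
    give stable rankings on desk-scale data.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if len(records) == 0:
        raise ValueError("empty record set")
    X = records.loc[:, list(features)].to_numpy(dtype=float)
    base = model.predict_proba(X)
    rng = np.random.default_rng(seed)
    if per_cell:
        if "cell_id" not in records:
            raise ValueError("per_cell permutation requires a cell_id column")
        groups = [
            np.nonzero((records["cell_id"] == cid).to_numpy())[0]
            for cid in records["cell_id"].unique()
        ]
    traces = np.empty((rounds, len(features)))
    for j in range(len(features)):
        for t in range(rounds):
            Xp = X.copy()
            if per_cell:
                for g in groups:
                    Xp[g, j] = X[rng.permutation(g), j]
            else:
                Xp[:, j] = X[rng.permutation(len(X)), j]
            probs = model.predict_proba(Xp)
            traces[t, j] = float(np.mean(np.abs(probs - base)))
    mae = traces.mean(axis=0)
    total = mae.sum()
    normalized = mae / total if total > 0 else np.full(len(features), 1.0 / len(features))
    return ImportanceResult(
        features=tuple(features), mae=mae, traces=traces, normalized=normalized
    )
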