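"""Prediction-quality metrics and parameter sensitivity sweeps.

The headline score is the mean absolute error between observed binary
annotations and predicted probabilities: 0 for perfect prediction, 0.5
for a coin toss, 1 for perfectly wrong.  It is threshold-free and robust
to class imbalance.  ROC/AUC is also provided, via the rank
(Mann-Whitney) formulation with midranks for ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .model import PARAM_NAMES, ModelParameters


@dataclass
class ScoreReport:
    """MAE/AUC summary over one set of scored annotations."""

    mae: float
    auc: Optional[float]
    n: int
    roc_points: Optional[List[Tuple[float, float]]] = None

    def to_json(self) -> str:
        return json.dumps({"mae": self.mae, "auc": self.auc, "n": self.n})


def mae(observed: Sequence[int], predicted: Sequence[float]) -> float:
    """Mean absolute error between binary observations and probabilities."""
    z = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if z.shape != p.shape or z.ndim != 1 or len(z) == 0:
        raise ValueError("observed and predicted must be equal-length 1-d vectors")
    if not np.isin(z, (0.0, 1.0)).all():
        raise ValueError("observed states must be binary")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return float(np.mean(np.abs(z - p)))


def roc_auc(observed: Sequence[int],
            predicted: Sequence[float]) -> Tuple[float, List[Tuple[float, float]]]:
    """AUC (Mann-Whitney with midranks) and the ROC threshold sweep."""
    z = np.asarray(observed, dtype=int)
    p = np.asarray(predicted, dtype=float)
    if len(set(z.tolist())) < 2:
        raise ValueError("AUC undefined: observed vector contains a single class")
    auc = float(roc_auc_score(z, p))
    fpr, tpr, _ = roc_curve(z, p)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def score_predictions(observed: Sequence[int],
                      predicted: Sequence[float]) -> ScoreReport:
    m = mae(observed, predicted)
    try:
        auc, points = roc_auc(observed, predicted)
    except ValueError:
        auc, points = None, None
    return ScoreReport(m, auc, len(list(observed)), points)


def sensitivity_sweep(data, params: ModelParameters, param_name: str,
                      grid: Sequence[float]) -> pd.DataFrame:
    """Leave-one-out MAE per tree while varying one parameter on a grid.

    For each grid value the named parameter is set (others fixed at
    ``params``), LOO predictions are recomputed for every annotated leaf
    of every triple in ``data``, and the per-tree MAE distribution is
    returned (columns: value, tree, mae).
    """
    from .prediction import loo_predictions  # local import avoids a cycle

    if param_name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {param_name!r}")
    for v in grid:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"grid value {v} outside [0, 1]")
    rows = []
    for value in grid:
        p = params.replace(**{param_name: float(value)})
        for idx, (tree, ann, function) in enumerate(data):
            if len(ann) == 0:
                continue
            tree_id = data.tree_ids[idx]
            loo = loo_predictions(tree, ann, p, function, tree_id=tree_id)
            rows.append({
                "value": float(value), "tree": tree_id,
                "mae": mae(loo["observed"].to_numpy(),
                           loo["posterior_prob"].to_numpy()),
            })
    return pd.DataFrame(rows, columns=["value", "tree", "mae"])
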