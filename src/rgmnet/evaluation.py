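"""Edge-recovery metrics for simulation studies.

Graphs are scored cell by cell over the p(p-1) off-diagonal positions:
confusion counts, TPR, FPR, FDR, Matthews correlation, and a ranking AUC
computed from the posterior inclusion probabilities by the Mann–Whitney
statistic (ties counted one half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricsReport", "classification_metrics", "auc_edge_ranking"]


@dataclass(frozen=True)
class MetricsReport:
    TP: int
    FP: int
    FN: int
    TN: int
    TPR: float
    FPR: float
    FDR: float
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "FN": self.FN, "TN": self.TN,
            "TPR": self.TPR, "FPR": self.FPR, "FDR": self.FDR,
            "MCC": self.MCC, "AUC": self.AUC,
        }


def _offdiag_values(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M)
    mask = ~np.eye(M.shape[0], dtype=bool)
    return M[mask]


def classification_metrics(
    z_pred: np.ndarray, gamma_true: np.ndarray, scores: np.ndarray | None = None
) -> MetricsReport:
    """Confusion counts and derived rates over off-diagonal cells.

    Zero-denominator conventions: MCC = 0 when any confusion marginal is
    zero; FDR = 0 when nothing is predicted positive; TPR is NaN when
    there are no true positives (FPR likewise with no true negatives).
    ``scores`` optionally adds the ranking AUC to the report.
    """
    z_pred = np.asarray(z_pred)
    gamma_true = np.asarray(gamma_true)
    if z_pred.shape != gamma_true.shape or z_pred.ndim != 2:
        raise ValueError("z_pred and gamma_true must be equal-shape square matrices")
    zp = _offdiag_values(z_pred).astype(bool)
    gt = _offdiag_values(gamma_true).astype(bool)
    TP = int(np.sum(zp & gt))
    FP = int(np.sum(zp & ~gt))
    FN = int(np.sum(~zp & gt))
    TN = int(np.sum(~zp & ~gt))
    TPR = TP / (TP + FN) if (TP + FN) else float("nan")
    FPR = FP / (FP + TN) if (FP + TN) else float("nan")
    FDR = FP / (TP + FP) if (TP + FP) else 0.0
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    MCC = (TP * TN - FP * FN) / math.sqrt(denom) if denom else 0.0
    AUC = auc_edge_ranking(scores, gamma_true) if scores is not None else None
    return MetricsReport(TP=TP, FP=FP, FN=FN, TN=TN, TPR=TPR, FPR=FPR,
                         FDR=FDR, MCC=MCC, AUC=AUC)


def auc_edge_ranking(scores: np.ndarray, gamma_true: np.ndarray) -> float:
    """Area under the ROC curve for ranking true edges above absent ones.

    Mann–Whitney formulation on the off-diagonal cells with midranks, so
    tied scores contribute one half; requires at least one edge and one
    non-edge in the truth.
    """
    s = _offdiag_values(np.asarray(scores, dtype=float))
    y = _offdiag_values(np.asarray(gamma_true)).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative cell")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
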