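"""Evaluation metrics: AUC, accuracy, F1 and recall for the positive class.

AUC is the rank-based probability that a random positive scores above a
random negative, with ties counted half — implemented directly from ranks so
tests can compare it against an exhaustive pairwise oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import rankdata


@dataclasses.dataclass
class EvalReport:
    auc: float
    acc: float
    f1: float
    recall: float
    split: str = ""
    n: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: split contains a single class")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_report(y_true: np.ndarray, prob_pos: np.ndarray,
                          split: str = "", threshold: float = 0.5) -> EvalReport:
    """All four study metrics from positive-class probabilities.

    F1 and recall are reported for the positive (severe-stenosis) class.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(prob_pos, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = float(np.mean(pred == y))
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return EvalReport(auc=auc_score(y, p), acc=acc, f1=f1, recall=float(recall),
                      split=split, n=len(y))
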