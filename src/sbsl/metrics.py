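"""Ranking metrics.

AUROC is the tie-corrected Mann-Whitney probability that a random positive
outranks a random negative; AUPRC is the interpolation-free step-curve sum
(average precision). Both require both classes to be present.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["auroc", "auprc"]


def _check(scores, y):
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("metric undefined: only one class present")
    return scores, y


def auroc(scores, y) -> float:
    scores, y = _check(scores, y)
    return float(roc_auc_score(y, scores))


def auprc(scores, y) -> float:
    scores, y = _check(scores, y)
    return float(average_precision_score(y, scores))
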