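"""Small shared statistics: rank-based AUC."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auc"]


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) identity.

    Probability that a randomly drawn positive outscores a randomly drawn
    negative, with ties counted as 1/2.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
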