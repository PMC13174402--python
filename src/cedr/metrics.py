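"""Partition-agreement metrics: NMI (primary), ARI, AMI, ACC.

NMI uses the geometric normalisation I(U,V) / sqrt(H(U) H(V)) with
natural-log entropies; ARI is the permutation-model adjusted Rand index,
AMI the expected-mutual-information adjustment, and ACC the accuracy
under the best one-to-one matching of predicted to true levels (solved
as a linear assignment problem).  All four are invariant to level
renaming; NMI/ARI/AMI are symmetric in their arguments.

When scoring a consensus or robust-clustering result against planted
truth, noise/trimmed samples keep their own predicted level (label 0 or
the TRIMMED sentinel) so that over-trimming is penalised rather than
silently ignored.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    normalized_mutual_info_score,
)
from sklearn.metrics.cluster import contingency_matrix

from .exceptions import ValidationError

__all__ = ["nmi", "ari", "ami", "acc", "score_partition"]


def _as_pair(labels_true, labels_pred) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(labels_true)
    v = np.asarray(labels_pred)
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError(
            f"partitions must be equal-length 1-d sequences, "
            f"got shapes {u.shape} and {v.shape}")
    if u.size == 0:
        raise ValidationError("empty partitions")
    return u, v


def _single_level(x: np.ndarray) -> bool:
    return np.unique(x).size < 2


def nmi(labels_true, labels_pred) -> float:
    """Normalized mutual information, geometric normalisation.

    Returns 0 (with a warning) when either partition has zero entropy,
    in which case the ratio is undefined.
    """
    u, v = _as_pair(labels_true, labels_pred)
    if _single_level(u) or _single_level(v):
        warnings.warn("NMI undefined for a zero-entropy partition; returning 0",
                      stacklevel=2)
        return 0.0
    return float(normalized_mutual_info_score(u, v, average_method="geometric"))


def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand index (can be negative; 1 iff identical partitions)."""
    u, v = _as_pair(labels_true, labels_pred)
    return float(adjusted_rand_score(u, v))


def ami(labels_true, labels_pred) -> float:
    """Adjusted mutual information (expected-MI correction, geometric mean)."""
    u, v = _as_pair(labels_true, labels_pred)
    if _single_level(u) or _single_level(v):
        warnings.warn("AMI undefined for a zero-entropy partition; returning 0",
                      stacklevel=2)
        return 0.0
    return float(adjusted_mutual_info_score(u, v, average_method="geometric"))


def acc(labels_true, labels_pred) -> float:
    """Clustering accuracy under optimal one-to-one level matching.

    Builds the contingency table and solves the maximum-agreement
    assignment; levels without a partner contribute zero.
    """
    u, v = _as_pair(labels_true, labels_pred)
    table = contingency_matrix(u, v)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / u.size)


def score_partition(labels_true, labels_pred) -> dict[str, float]:
    """All four metrics for one (truth, prediction) pair."""
    return {
        "NMI": nmi(labels_true, labels_pred),
        "ARI": ari(labels_true, labels_pred),
        "AMI": ami(labels_true, labels_pred),
        "ACC": acc(labels_true, labels_pred),
    }
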