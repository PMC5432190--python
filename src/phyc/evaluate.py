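"""External clustering validation: purity, NMI and the Rand index.

All three compare a predicted partition with ground-truth classes and live
in [0, 1].  Purity is the fraction of objects assigned to their cluster's
majority class (not symmetric in its arguments; an all-singleton prediction
trivially scores 1).  NMI normalizes the mutual information by the
arithmetic mean of the two partition entropies by default (a square-root
normalization is one flag away).  The Rand index is the fraction of object
pairs on which the two partitions agree (co-clustered in both or separated
in both).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import normalized_mutual_info_score, rand_score
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["EvalScores", "purity", "nmi", "rand_index", "evaluate_clustering"]


def _check_pair(pred, true) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D and equal length; got {pred.shape} "
            f"and {true.shape}"
        )
    if len(pred) == 0:
        raise ValueError("empty labelings")
    return pred, true


def purity(pred_labels, true_labels) -> float:
    """(1/n) sum over clusters of the majority-class overlap."""
    pred, true = _check_pair(pred_labels, true_labels)
    table = contingency_matrix(true, pred)  # classes x clusters
    return float(table.max(axis=0).sum() / len(pred))


def nmi(pred_labels, true_labels, normalization: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions.

    ``normalization`` is ``"arithmetic"`` (default; mean of the entropies) or
    ``"sqrt"`` (geometric mean).  Two trivial single-cluster partitions are
    identical, so that degenerate 0/0 case scores 1; a single-cluster
    prediction against a multi-class truth scores 0.
    """
    pred, true = _check_pair(pred_labels, true_labels)
    if normalization not in ("arithmetic", "sqrt"):
        raise ValueError("normalization must be 'arithmetic' or 'sqrt'")
    n_pred = len(np.unique(pred))
    n_true = len(np.unique(true))
    if n_pred == 1 and n_true == 1:
        return 1.0
    if n_pred == 1 or n_true == 1:
        return 0.0
    method = "arithmetic" if normalization == "arithmetic" else "geometric"
    return float(normalized_mutual_info_score(true, pred, average_method=method))


def rand_index(pred_labels, true_labels) -> float:
    """Fraction of object pairs treated concordantly by both partitions."""
    pred, true = _check_pair(pred_labels, true_labels)
    if len(pred) < 2:
        raise ValueError("the Rand index needs at least two objects")
    return float(rand_score(true, pred))


@dataclass(frozen=True)
class EvalScores:
    """Purity / NMI / Rand triple with the underlying contingency table."""

    purity: float
    nmi: float
    rand: float
    contingency: np.ndarray  # predicted clusters x true classes

    def as_dict(self) -> dict[str, float]:
        return {"purity": self.purity, "nmi": self.nmi, "rand": self.rand}


def evaluate_clustering(pred_labels, true_labels) -> EvalScores:
    """All three indices of a predicted partition against the truth."""
    pred, true = _check_pair(pred_labels, true_labels)
    table = contingency_matrix(pred, true)
    scores = EvalScores(
        purity=purity(pred, true),
        nmi=nmi(pred, true),
        rand=rand_index(pred, true) if len(pred) >= 2 else 1.0,
        contingency=table,
    )
    return scores
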