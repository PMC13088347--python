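"""Binary-classifier evaluation and contact-map precision.

AUROC follows the Mann-Whitney convention: the probability that a
random positive outscores a random negative, with half credit for
ties, which makes it invariant under strictly monotone transforms of
the scores.  F1 is evaluated at a fixed decision threshold (0.5 unless
overridden) and is 0 when positives exist but nothing is predicted
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .structure import ResidueContactMatrix


class MetricError(ValueError):
    """Single-class input or otherwise unevaluable metric request."""


@dataclass(frozen=True)
class EvaluationResult:
    metric: str
    value: float
    n: int
    n_positive: int
    threshold: float | None = None
    config: dict = field(default_factory=dict)


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricError("scores and labels must be equal-length 1-D arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise MetricError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise MetricError("both classes must be present")
    return scores, labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve, P(score+ > score-) + 0.5 P(tie)."""
    scores, labels = _check_binary(scores, labels)
    return float(roc_auc_score(labels, scores))


def f1(scores, labels, threshold: float = 0.5) -> float:
    """F1 at a hard threshold (prediction positive iff score >= threshold)."""
    scores, labels = _check_binary(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def evaluate_scores(scores, labels, threshold: float = 0.5) -> dict[str, EvaluationResult]:
    """AUROC + F1 bundle for a scored binary dataset."""
    scores_a, labels_a = _check_binary(scores, labels)
    n = len(labels_a)
    npos = int(labels_a.sum())
    return {
        "auroc": EvaluationResult("auroc", auroc(scores_a, labels_a), n, npos),
        "f1": EvaluationResult("f1", f1(scores_a, labels_a, threshold), n, npos,
                               threshold=threshold),
    }


def topk_contact_precision(
    pred_entries: np.ndarray,
    truth: ResidueContactMatrix,
    k: int,
    min_separation: int = 6,
) -> float:
    """Precision of the k most confident predicted contacts.

    Eligible pairs are off-diagonal upper-triangle pairs (i < j,
    0-based) with ``j - i >= min_separation`` and both residues
    unmasked.  The top k are chosen by descending probability with ties
    broken by (lower i, lower j); precision is the fraction of chosen
    pairs that are true contacts.
    """
    pred = np.asarray(pred_entries, dtype=float)
    n = truth.n
    if pred.shape != (n, n):
        raise MetricError(f"prediction shape {pred.shape} != truth shape {(n, n)}")
    if k < 1:
        raise MetricError("k must be a positive integer")
    min_separation = max(int(min_separation), 1)  # 0 still excludes the diagonal

    iu, ju = np.triu_indices(n, k=min_separation)
    eligible = truth.mask[iu] & truth.mask[ju]
    iu, ju = iu[eligible], ju[eligible]
    if iu.size < k:
        raise MetricError(
            f"only {iu.size} eligible pairs after separation filtering, need k={k}"
        )
    order = np.lexsort((ju, iu, -pred[iu, ju]))[:k]
    hits = truth.entries[iu[order], ju[order]]
    return float(np.mean(hits))
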