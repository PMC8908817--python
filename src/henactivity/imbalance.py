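"""Inverse-class-frequency misclassification penalties.

With ~37 highly dynamic windows against ~6600 static/semi-dynamic ones, an
unweighted learner can ignore the rare class almost for free.  The penalty
of misclassifying a sample of class i is

    penalty_i = n_total / n_class_i,

so penalty_i * n_class_i = n_total for every class: each class carries the
same total misclassification budget.  The structure is exposed both as a
K x K cost matrix (rows = true class, columns = predicted class, zero
diagonal, row-constant off-diagonal cost penalty_i) and as a per-class
weight vector for trainers that take sample/class weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["PenaltyMatrix", "compute_penalties"]


@dataclass
class PenaltyMatrix:
    classes: list[int]
    class_counts: np.ndarray
    n_total: int
    matrix: np.ndarray  #: (K, K) cost matrix

    @property
    def penalties(self) -> np.ndarray:
        """Per-class penalty vector n_total / n_class_i."""
        return self.n_total / self.class_counts

    @property
    def weights(self) -> dict[int, float]:
        """Class -> penalty mapping, for weight-based trainers."""
        return {c: float(p) for c, p in zip(self.classes, self.penalties)}


def compute_penalties(class_counts: Mapping[int, int] | Sequence[int]) -> PenaltyMatrix:
    """Build the penalty structure from per-class training counts."""
    if isinstance(class_counts, Mapping):
        classes = sorted(class_counts)
        counts = np.array([class_counts[c] for c in classes], dtype=float)
    else:
        counts = np.asarray(class_counts, dtype=float)
        classes = list(range(1, counts.size + 1))
    if counts.size == 0:
        raise ValueError("need at least one class")
    if np.any(counts <= 0):
        raise ValueError("class absent from training data")
    n_total = counts.sum()
    penalties = n_total / counts
    k = counts.size
    matrix = np.tile(penalties[:, None], (1, k))
    np.fill_diagonal(matrix, 0.0)
    return PenaltyMatrix(
        classes=classes,
        class_counts=counts,
        n_total=int(n_total),
        matrix=matrix,
    )
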