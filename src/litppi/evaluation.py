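"""Scoring predicted complexes against a reference catalog.

Three complementary families of measures are implemented:

* the pairwise **overlap score** omega(A, B) = |A ∩ B|^2 / (|A| x |B|)
  (also called the neighborhood affinity score) and the **matched fraction**
  of predictions reaching omega >= 0.25 against some reference complex;
* the **clustering-wise sensitivity (Sn)**, **positive predictive value
  (PPV)** and their geometric mean, the **geometric accuracy (Acc)**,
  computed from the reference-by-prediction shared-protein confusion matrix;
* the **maximum matching ratio (MMR)**: the total overlap-score weight of a
  maximum-weight one-to-one matching between reference and predicted
  complexes, divided by the number of reference complexes.  Because gold
  standards are incomplete, MMR — unlike Acc — does not penalize predictions
  that match nothing, which makes it the headline metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .complexes import ComplexSet

logger = logging.getLogger(__name__)

__all__ = [
    "overlap_score",
    "fraction_matched",
    "ConfusionMatrix",
    "confusion_matrix",
    "clustering_wise_sn",
    "clustering_wise_ppv",
    "geometric_accuracy",
    "mmr",
    "mmr_rowmax",
    "EvaluationResult",
    "evaluate_all",
]


def overlap_score(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Overlap score omega(A, B) = |A ∩ B|^2 / (|A| * |B|).

    Symmetric; 1 iff the sets are equal, 0 iff they are disjoint.  The
    customary match threshold 0.25 corresponds to two equally large sets
    sharing half their members.
    """
    if not a or not b:
        raise ValueError("overlap score is undefined for empty sets")
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


def fraction_matched(
    pred: ComplexSet, ref: ComplexSet, omega_min: float = 0.25
) -> tuple[int, int]:
    """Count predictions matching at least one reference at omega >= omega_min.

    Returns ``(n_clusters, n_matched)`` — the total number of predictions and
    how many of them reach the overlap threshold against some reference
    complex.  The boundary is inclusive.
    """
    n_matched = 0
    for p in pred.members:
        if any(overlap_score(p, r) >= omega_min for r in ref.members):
            n_matched += 1
    return len(pred), n_matched


@dataclass
class ConfusionMatrix:
    """Reference-by-prediction shared-protein counts.

    ``T[i, j]`` is the number of proteins occurring in both reference complex
    i and predicted complex j; ``N[i]`` is the size of reference complex i.
    """

    T: np.ndarray  # shape (n_ref, n_pred), integer counts
    N: np.ndarray  # shape (n_ref,), reference complex sizes

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=np.int64).reshape(len(self.N), -1) if np.size(self.T) else np.zeros((len(self.N), 0), dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        if (self.T < 0).any() or (self.N < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def column_sums(self) -> np.ndarray:
        """T.j — the number of shared-protein assignments per predicted complex."""
        return self.T.sum(axis=0)


def confusion_matrix(ref: ComplexSet, pred: ComplexSet) -> ConfusionMatrix:
    """Build the shared-protein confusion matrix T with T[i,j] = |ref_i ∩ pred_j|."""
    n, m = len(ref), len(pred)
    T = np.zeros((n, m), dtype=np.int64)
    for i, r in enumerate(ref.members):
        for j, p in enumerate(pred.members):
            T[i, j] = len(r & p)
    N = np.array([len(r) for r in ref.members], dtype=np.int64)
    return ConfusionMatrix(T=T, N=N)


def clustering_wise_sn(cm: ConfusionMatrix) -> float:
    """Sn = sum_i max_j T_ij / sum_i N_i — coverage of reference proteins.

    Equals 1 iff every reference complex is entirely contained in some single
    prediction.
    """
    if cm.N.sum() == 0:
        raise ValueError("clustering-wise Sn is undefined without reference complexes")
    if cm.T.shape[1] == 0:
        return 0.0
    return float(cm.T.max(axis=1).sum() / cm.N.sum())


def clustering_wise_ppv(cm: ConfusionMatrix) -> float:
    """PPV = sum_j max_i T_ij / sum_j T.j — reliability of the predictions.

    When no prediction shares a single protein with any reference the
    denominator vanishes; 0 is returned with a warning.
    """
    denom = cm.column_sums.sum()
    if denom == 0:
        logger.warning("every prediction is disjoint from every reference; PPV defined as 0")
        return 0.0
    return float(cm.T.max(axis=0).sum() / denom)


def geometric_accuracy(sn: float, ppv: float) -> float:
    """Acc = sqrt(Sn x PPV), the geometric mean balancing coverage and reliability."""
    return math.sqrt(sn * ppv)


def _omega_matrix(ref: ComplexSet, pred: ComplexSet) -> np.ndarray:
    W = np.zeros((len(ref), len(pred)))
    for i, r in enumerate(ref.members):
        for j, p in enumerate(pred.members):
            inter = len(r & p)
            if inter:
                W[i, j] = inter * inter / (len(r) * len(p))
    return W


def mmr(pred: ComplexSet, ref: ComplexSet) -> float:
    """Maximum matching ratio between predictions and references.

    Form the bipartite graph connecting reference complex i to predicted
    complex j with weight omega(i, j) whenever the overlap score is positive;
    MMR is the total weight of a maximum-weight one-to-one matching divided by
    the number of reference complexes.
    """
    if len(ref) == 0:
        raise ValueError("MMR is undefined without reference complexes")
    if len(pred) == 0:
        return 0.0
    W = _omega_matrix(ref, pred)
    rows, cols = linear_sum_assignment(W, maximize=True)
    return float(W[rows, cols].sum() / len(ref))


def mmr_rowmax(pred: ComplexSet, ref: ComplexSet) -> float:
    """Row-maximum diagnostic variant: sum_i max_j omega(i, j) / n.

    Ignores the one-to-one constraint, so it upper-bounds :func:`mmr`; the two
    agree whenever the per-reference best predictions are all distinct.
    """
    if len(ref) == 0:
        raise ValueError("MMR is undefined without reference complexes")
    if len(pred) == 0:
        return 0.0
    W = _omega_matrix(ref, pred)
    return float(W.max(axis=1).sum() / len(ref))


@dataclass
class EvaluationResult:
    """Bundle of all quality measures for one prediction/reference pairing."""

    sn: float
    ppv: float
    acc: float
    mmr: float
    n_clusters: int
    n_matched: int

    def __post_init__(self):
        for name in ("sn", "ppv", "acc", "mmr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_matched > self.n_clusters:
            raise ValueError("n_matched cannot exceed n_clusters")

    def as_dict(self) -> dict:
        return {
            "sn": self.sn,
            "ppv": self.ppv,
            "acc": self.acc,
            "mmr": self.mmr,
            "n_clusters": self.n_clusters,
            "n_matched": self.n_matched,
        }


def evaluate_all(
    pred: ComplexSet, ref: ComplexSet, omega_min: float = 0.25
) -> EvaluationResult:
    """Compute Sn, PPV, Acc, MMR and the matched fraction in one pass."""
    if len(ref) == 0:
        raise ValueError("evaluation requires a non-empty reference set")
    cm = confusion_matrix(ref, pred)
    sn = clustering_wise_sn(cm)
    ppv = clustering_wise_ppv(cm)
    acc = geometric_accuracy(sn, ppv)
    m = mmr(pred, ref)
    n_clusters, n_matched = fraction_matched(pred, ref, omega_min=omega_min)
    return EvaluationResult(sn=sn, ppv=ppv, acc=acc, mmr=m, n_clusters=n_clusters, n_matched=n_matched)
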