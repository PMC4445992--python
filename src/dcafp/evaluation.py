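"""Assessment of predicted complexes against a reference catalog.

Three complementary measure families are provided:

* **f-measure** — a prediction matches a reference complex when the
  neighborhood-affinity matching rate |A∩B|²/(|A||B|) reaches a threshold
  (0.2 by convention). TP counts predictions with at least one match, FP
  those with none, FN the reference complexes left unmatched;
  precision = TP/(TP+FP), recall = (#matched references)/(#references) and
  f is their harmonic mean. Counting matched references (rather than TP) in
  the recall numerator keeps recall ≤ 1 when several predictions hit the
  same reference complex.
* **Accuracy** — geometric mean of clustering-wise sensitivity Sn and
  positive predictive value PPV computed from the reference × prediction
  overlap contingency table.
* **MMR** — total weight of a maximum one-to-one matching between reference
  and predicted complexes (edge weight = matching rate), normalized by the
  number of reference complexes.

A plain Jaccard matching rate is available behind ``method="jaccard"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import ClusterSet

MATCH_METHODS = ("affinity", "jaccard")

#: conventional minimum matching rate for a prediction to count as a hit
DEFAULT_MATCH_THRESHOLD = 0.2


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    sn: float
    ppv: float
    accuracy: float
    mmr: float
    overlap_pair_fraction: float
    coverage: int
    n_predicted: int
    n_reference: int
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "sn": self.sn,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "mmr": self.mmr,
            "overlap_pair_fraction": self.overlap_pair_fraction,
            "coverage": self.coverage,
            "n_predicted": self.n_predicted,
            "n_reference": self.n_reference,
            "flags": self.flags,
        }


def matching_rate(
    pred: frozenset | set, ref: frozenset | set, method: str = "affinity"
) -> float:
    """Neighborhood affinity |∩|²/(|pred|·|ref|), or Jaccard."""
    if not pred or not ref:
        raise ValueError("clusters must be nonempty")
    inter = len(set(pred) & set(ref))
    if method == "affinity":
        return inter * inter / (len(pred) * len(ref))
    if method == "jaccard":
        return inter / (len(pred) + len(ref) - inter)
    raise ValueError(f"method must be one of {MATCH_METHODS}")


def _rate_matrix(
    reference: Sequence[frozenset], predicted: Sequence[frozenset], method: str
) -> np.ndarray:
    M = np.zeros((len(reference), len(predicted)))
    for i, ref in enumerate(reference):
        for j, pred in enumerate(predicted):
            M[i, j] = matching_rate(pred, ref, method=method)
    return M


def precision_recall_f(
    predicted: ClusterSet,
    reference: ClusterSet,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    method: str = "affinity",
) -> tuple[float, float, float]:
    """(precision, recall, f) at the given matching-rate threshold."""
    p, r, f, *_ = _prf_detail(predicted, reference, threshold, method)
    return p, r, f


def _prf_detail(
    predicted: ClusterSet,
    reference: ClusterSet,
    threshold: float,
    method: str,
) -> tuple[float, float, float, int, int, int, list[tuple[int, int, float]]]:
    preds = list(predicted)
    refs = list(reference)
    if not preds:
        return 0.0, 0.0, 0.0, 0, 0, len(refs), []
    M = _rate_matrix(refs, preds, method)
    hits = M >= threshold
    tp = int(np.sum(hits.any(axis=0)))
    fp = len(preds) - tp
    matched_refs = int(np.sum(hits.any(axis=1)))
    fn = len(refs) - matched_refs
    precision = tp / (tp + fp)
    recall = matched_refs / len(refs) if refs else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    pairs = [
        (int(j), int(i), float(M[i, j])) for i, j in zip(*np.nonzero(hits))
    ]
    return precision, recall, f, tp, fp, fn, pairs


def accuracy(
    predicted: ClusterSet, reference: ClusterSet
) -> tuple[float, float, float]:
    """(Sn, PPV, Acc) from the reference × prediction contingency table.

    Sn = Σ_i max_j t_ij / Σ_i |ref_i| and PPV = Σ_j max_i t_ij / Σ_ij t_ij,
    where t_ij = |ref_i ∩ pred_j|; predictions overlapping no reference
    complex contribute nothing to either PPV sum. Acc = sqrt(Sn · PPV).
    """
    refs = list(reference)
    preds = list(predicted)
    t = np.zeros((len(refs), len(preds)))
    for i, ref in enumerate(refs):
        for j, pred in enumerate(preds):
            t[i, j] = len(ref & pred)
    ref_sizes = sum(len(ref) for ref in refs)
    sn = float(t.max(axis=1).sum() / ref_sizes) if ref_sizes and preds else 0.0
    total = float(t.sum())
    ppv = float(t.max(axis=0).sum() / total) if total else 0.0
    return sn, ppv, float(np.sqrt(sn * ppv))


def mmr(
    predicted: ClusterSet,
    reference: ClusterSet,
    method: str = "affinity",
) -> float:
    """Maximum matching rate: optimal one-to-one assignment weight over
    |reference|."""
    refs = list(reference)
    preds = list(predicted)
    if not refs:
        raise ValueError("reference catalog is empty")
    if not preds:
        return 0.0
    M = _rate_matrix(refs, preds, method)
    rows, cols = linear_sum_assignment(M, maximize=True)
    return float(M[rows, cols].sum() / len(refs))


def overlap_pair_fraction(clusters: ClusterSet) -> float:
    """Fraction of unordered cluster pairs sharing at least one protein;
    0 (flagged upstream) when fewer than two clusters exist."""
    members = list(clusters)
    n = len(members)
    if n < 2:
        return 0.0
    overlapping = sum(
        1
        for p in range(n)
        for q in range(p + 1, n)
        if members[p] & members[q]
    )
    return overlapping / (n * (n - 1) / 2)


def coverage(predicted: ClusterSet) -> int:
    """Number of distinct proteins appearing in any predicted complex."""
    seen: set[str] = set()
    for c in predicted:
        seen |= c
    return len(seen)


def evaluate(
    predicted: ClusterSet,
    reference: ClusterSet,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    method: str = "affinity",
) -> EvaluationReport:
    """Full report combining every measure above."""
    flags: list[str] = []
    if len(predicted) == 0:
        flags.append("no predicted clusters: precision reported as 0")
    if len(predicted) < 2:
        flags.append("fewer than 2 predicted clusters: overlap fraction is 0")
    precision, recall, f, tp, fp, fn, pairs = _prf_detail(
        predicted, reference, threshold, method
    )
    sn, ppv, acc = accuracy(predicted, reference)
    mmr_score = mmr(predicted, reference, method) if len(predicted) else 0.0
    return EvaluationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f_measure=f,
        sn=sn,
        ppv=ppv,
        accuracy=acc,
        mmr=mmr_score,
        overlap_pair_fraction=overlap_pair_fraction(predicted),
        coverage=coverage(predicted),
        n_predicted=len(predicted),
        n_reference=len(reference),
        matched_pairs=pairs,
        flags=flags,
    )
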