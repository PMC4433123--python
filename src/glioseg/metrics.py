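"""Segmentation evaluation: BRATS compartments, Dice, PPV, sensitivity, kappa.

Compartments over the BRATS label codes:
``complete`` = {1, 2, 3, 4}, ``core`` = {1, 3, 4}, ``enhancing`` = {4}.

Dice is the standard overlap coefficient 2TP/(P + P_hat).  A historical
variant ``2(TP+TN)/(P+N+P_hat+N_hat)`` — an accuracy-like quantity that
appears in some method write-ups — is available as ``variant="printed"``
for auditability but is not used for reporting.

Cohen's kappa is computed on the binary compartment masks through
P_A = (TP+TN)/(P+N) and
P_E = (P/(P+N)) * (P_hat/(P_hat+N_hat)) + (N/(P+N)) * (N_hat/(P_hat+N_hat)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume_io import LabelVolume

logger = logging.getLogger(__name__)

COMPARTMENTS = {
    "complete": frozenset({1, 2, 3, 4}),
    "core": frozenset({1, 3, 4}),
    "enhancing": frozenset({4}),
}


@dataclass
class EvaluationCounts:
    """Binary confusion counts over the evaluated voxels."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:       # reference positives
        return self.tp + self.fn

    @property
    def n(self) -> int:       # reference negatives
        return self.tn + self.fp

    @property
    def p_hat(self) -> int:   # predicted positives
        return self.tp + self.fp

    @property
    def n_hat(self) -> int:   # predicted negatives
        return self.tn + self.fn

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class CompartmentReport:
    """Dice/PPV/sensitivity per compartment plus complete-tumour kappa."""

    scores: dict[str, dict[str, float]]
    kappa: float

    def as_flat_dict(self) -> dict[str, float]:
        out = {f"{comp}_{metric}": val
               for comp, metrics in self.scores.items()
               for metric, val in metrics.items()}
        out["kappa"] = self.kappa
        return out


def binarize_compartment(labels: LabelVolume | np.ndarray, compartment: str) -> np.ndarray:
    """Binary mask of one BRATS compartment."""
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}; "
                         f"choose from {sorted(COMPARTMENTS)}")
    arr = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    return np.isin(arr, sorted(COMPARTMENTS[compartment]))


def confusion_counts(predicted: np.ndarray, reference: np.ndarray,
                     eval_mask: np.ndarray | None = None) -> EvaluationCounts:
    """Binary confusion counts, restricted to ``eval_mask`` if given."""
    predicted = np.asarray(predicted) > 0
    reference = np.asarray(reference) > 0
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference shapes differ")
    if eval_mask is None:
        eval_mask = np.ones(predicted.shape, dtype=bool)
    else:
        eval_mask = np.asarray(eval_mask) > 0
        if eval_mask.shape != predicted.shape:
            raise ValueError("eval mask shape differs")
    pr = predicted[eval_mask]
    re = reference[eval_mask]
    return EvaluationCounts(tp=int((pr & re).sum()), tn=int((~pr & ~re).sum()),
                            fp=int((pr & ~re).sum()), fn=int((~pr & re).sum()))


def dice(counts: EvaluationCounts, variant: str = "overlap") -> float:
    """Dice coefficient.

    ``overlap`` (default): 2TP/(P + P_hat), 1 if both sets are empty.
    ``printed``: 2(TP+TN)/(P+N+P_hat+N_hat).
    """
    if variant == "printed":
        denom = counts.p + counts.n + counts.p_hat + counts.n_hat
        return 2.0 * (counts.tp + counts.tn) / denom if denom else 1.0
    if variant != "overlap":
        raise ValueError("variant must be 'overlap' or 'printed'")
    denom = counts.p + counts.p_hat
    if denom == 0:
        logger.info("dice: both masks empty, returning 1 by convention")
        return 1.0
    return 2.0 * counts.tp / denom


def ppv(counts: EvaluationCounts) -> float:
    """Positive predictive value TP/(TP+FP); 1 when nothing was predicted."""
    denom = counts.tp + counts.fp
    if denom == 0:
        logger.info("ppv: no predicted positives, returning 1 by convention")
        return 1.0
    return counts.tp / denom


def sensitivity(counts: EvaluationCounts) -> float:
    """Sensitivity TP/(TP+FN); 1 when the reference is empty."""
    denom = counts.tp + counts.fn
    if denom == 0:
        logger.info("sensitivity: empty reference, returning 1 by convention")
        return 1.0
    return counts.tp / denom


def kappa(counts: EvaluationCounts) -> float:
    """Cohen's kappa (P_A - P_E)/(1 - P_E); 0 when P_E degenerates to 1."""
    total = counts.total
    if total == 0:
        return 0.0
    p_a = (counts.tp + counts.tn) / total
    p_e = (counts.p / total) * (counts.p_hat / total) + \
          (counts.n / total) * (counts.n_hat / total)
    if abs(1.0 - p_e) < 1e-15:
        logger.info("kappa: P_E = 1 (single-class degenerate), returning 0")
        return 0.0
    return (p_a - p_e) / (1.0 - p_e)


def evaluate_segmentation(predicted: LabelVolume, reference: LabelVolume,
                          eval_mask: np.ndarray | None = None) -> CompartmentReport:
    """Per-compartment Dice/PPV/sensitivity plus complete-tumour kappa."""
    scores = {}
    for comp in COMPARTMENTS:
        c = confusion_counts(binarize_compartment(predicted, comp),
                             binarize_compartment(reference, comp), eval_mask)
        scores[comp] = {"dice": dice(c), "ppv": ppv(c), "sensitivity": sensitivity(c)}
    complete = confusion_counts(binarize_compartment(predicted, "complete"),
                                binarize_compartment(reference, "complete"), eval_mask)
    return CompartmentReport(scores=scores, kappa=kappa(complete))
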