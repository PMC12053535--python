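"""Dice similarity (DSC), aggregated Dice (DSCagg), and the present-class Dice loss.

For one class with binary ground truth ``y`` and prediction ``y_hat``::

    DSC(y, y_hat) = 2 |y ∩ y_hat| / (|y| + |y_hat|)

DSC is uninformative on tumor-free patients (it is 0 for any non-empty
prediction), so cohort evaluation pools intersections and sizes over all
N pairs before dividing::

    DSCagg = 2 Σ_n |y_n ∩ y_hat_n| / Σ_n (|y_n| + |y_hat_n|)

Patients with empty ground truth then still penalize false positives
through the denominator. The training loss is the smooth analogue of
1 − DSCagg per class, computed over the whole batch with soft
probabilities, and averaged only over classes actually present in the
batch's ground truth (background included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationSet",
    "dsc",
    "dsc_agg",
    "dice_loss",
    "cohort_score",
    "evaluate_cohort",
]

#: epsilon guarding an all-zero soft denominator in the Dice loss
LOSS_EPS = 1e-7

CLASS_NAMES = {1: "GTVp", 2: "GTVn"}


@dataclass
class EvaluationSet:
    """Pairs of (binary ground truth, binary prediction) for one class."""

    pairs: Sequence[tuple[np.ndarray, np.ndarray]]


def _check_binary(y, y_hat):
    y = np.asarray(y)
    y_hat = np.asarray(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    for name, m in (("ground truth", y), ("prediction", y_hat)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary (values {vals[:5]}...)")
    return y.astype(bool), y_hat.astype(bool)


def dsc(y, y_hat, empty_value: float = 1.0) -> float:
    """Dice similarity coefficient of two binary masks.

    ``empty_value`` is returned when both masks are empty (a vacuously
    perfect prediction, the per-patient reporting convention); when exactly
    one is empty the score is 0.
    """
    y, y_hat = _check_binary(y, y_hat)
    denom = int(y.sum()) + int(y_hat.sum())
    if denom == 0:
        return float(empty_value)
    return 2.0 * int((y & y_hat).sum()) / denom


def dsc_agg(pairs, empty_value: float = 1.0) -> float:
    """Aggregated Dice over a set of (truth, prediction) binary mask pairs.

    Intersections and mask sizes are summed over all pairs before the
    ratio, so pairs with empty ground truth contribute their predicted
    volume to the denominator. ``pairs`` may be an :class:`EvaluationSet`
    or any iterable of pairs. An all-empty set returns ``empty_value``.
    """
    if isinstance(pairs, EvaluationSet):
        pairs = pairs.pairs
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty evaluation set")
    inter = 0
    sizes = 0
    for y, y_hat in pairs:
        y, y_hat = _check_binary(y, y_hat)
        inter += int((y & y_hat).sum())
        sizes += int(y.sum()) + int(y_hat.sum())
    if sizes == 0:
        return float(empty_value)
    return 2.0 * inter / sizes


def dice_loss(truths: np.ndarray, probs: np.ndarray) -> float:
    """Batch Dice loss averaged over classes present in the ground truth.

    Parameters
    ----------
    truths
        One-hot ground truth, shape ``(N, C, ...)``.
    probs
        Predicted class probabilities in [0, 1], same shape, summing to 1
        over the class axis.

    Per class ``c`` with ``Σ y_c > 0`` the term is
    ``1 − 2 Σ y_c p_c / (Σ y_c + Σ p_c)`` pooled over the whole batch;
    absent classes contribute nothing and the loss is the mean of the
    present-class terms.
    """
    truths = np.asarray(truths, dtype=np.float64)
    probs = np.asarray(probs, dtype=np.float64)
    if truths.shape != probs.shape:
        raise ValueError(f"shape mismatch: {truths.shape} vs {probs.shape}")
    if probs.min() < -1e-6 or probs.max() > 1 + 1e-6:
        raise ValueError("probabilities outside [0, 1]")
    n_classes = truths.shape[1]
    axes = (0,) + tuple(range(2, truths.ndim))
    y_sum = truths.sum(axis=axes)
    if not np.any(y_sum > 0):
        raise ValueError("ground truth contains no class at all")
    terms = []
    for c in range(n_classes):
        if y_sum[c] == 0:
            continue
        inter = (truths[:, c] * probs[:, c]).sum()
        denom = y_sum[c] + probs[:, c].sum() + LOSS_EPS
        terms.append(1.0 - 2.0 * inter / denom)
    return float(np.mean(terms))


def cohort_score(truth_masks, pred_masks, classes=(1, 2)) -> float:
    """Mean of per-class DSCagg over the tumor classes (GTVp, GTVn)."""
    per_class = [
        dsc_agg([(t == c, p == c) for t, p in zip(truth_masks, pred_masks)])
        for c in classes
    ]
    return float(np.mean(per_class))


def _precision_recall(y, y_hat):
    tp = int((y & y_hat).sum())
    fp = int((~y & y_hat).sum())
    fn = int((y & ~y_hat).sum())
    prec = tp / (tp + fp) if tp + fp else np.nan
    rec = tp / (tp + fn) if tp + fn else np.nan
    return prec, rec


def evaluate_cohort(truths, preds, patient_ids=None, classes=(1, 2)) -> pd.DataFrame:
    """Per-patient DSC/precision/recall plus cohort DSCagg per class.

    ``truths`` and ``preds`` are sequences of integer label arrays. Returns
    a tidy frame with one row per (patient, class) and summary rows
    (``patient == "DSCagg"``) holding the pooled cohort score per class.
    """
    truths = list(truths)
    preds = list(preds)
    if len(truths) != len(preds):
        raise ValueError("truth/prediction count mismatch")
    if patient_ids is None:
        patient_ids = [f"patient_{i:03d}" for i in range(len(truths))]
    rows = []
    for pid, t, p in zip(patient_ids, truths, preds):
        t = np.asarray(t)
        p = np.asarray(p)
        for c in classes:
            y, y_hat = (t == c), (p == c)
            prec, rec = _precision_recall(y, y_hat)
            rows.append(
                {
                    "patient": pid,
                    "class": CLASS_NAMES.get(c, str(c)),
                    "dsc": dsc(y, y_hat),
                    "precision": prec,
                    "recall": rec,
                    "truth_voxels": int(y.sum()),
                    "pred_voxels": int(y_hat.sum()),
                }
            )
    for c in classes:
        rows.append(
            {
                "patient": "DSCagg",
                "class": CLASS_NAMES.get(c, str(c)),
                "dsc": dsc_agg([(np.asarray(t) == c, np.asarray(p) == c) for t, p in zip(truths, preds)]),
                "precision": np.nan,
                "recall": np.nan,
                "truth_voxels": sum(int((np.asarray(t) == c).sum()) for t in truths),
                "pred_voxels": sum(int((np.asarray(p) == c).sum()) for p in preds),
            }
        )
    return pd.DataFrame(rows)
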