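"""Evaluation metrics: ROC AUC (rank statistic), balanced accuracy, FPR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["EvalMetrics", "roc_auc", "confusion_metrics", "evaluate_corpus"]


@dataclass
class EvalMetrics:
    auc: float
    ba: float
    sensitivity: float
    specificity: float
    fpr: float
    n_pos: int
    n_neg: int
    threshold: float


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney rank statistic; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def confusion_metrics(scores, labels, threshold: float) -> EvalMetrics:
    """Rates at a fixed threshold; a call is positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    calls = scores >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    fp = int(np.sum(calls & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalMetrics(
        auc=roc_auc(scores, labels),
        ba=(sens + spec) / 2,
        sensitivity=sens,
        specificity=spec,
        fpr=1.0 - spec,
        n_pos=tp + fn,
        n_neg=tn + fp,
        threshold=threshold,
    )


def evaluate_corpus(predictions, labelings, threshold: float = 0.5, pooling: str = "pooled") -> dict:
    """Per-structure metric table plus pooled-residue metrics.

    ``predictions`` are :class:`glycep.model.PredictionResult` objects;
    ``labelings`` the matching :class:`EpitopeLabeling` objects. Structures
    whose labels are single-class are reported as NA and excluded from the
    per-structure AUC average; pooled metrics concatenate all residues.
    """
    lab_by_key = {lab.structure_key: lab for lab in labelings}
    rows = []
    all_scores, all_labels = [], []
    for pred in predictions:
        if pred.structure_key not in lab_by_key:
            raise KeyError(f"no labeling for structure {pred.structure_key}")
        lab = lab_by_key[pred.structure_key]
        surf = pred.rows[pred.rows["is_surface"]]
        scores = surf["adjusted_score"].to_numpy()
        labels = np.array([lab.labels[i] for i in surf.index], dtype=int)
        all_scores.append(scores)
        all_labels.append(labels)
        if len(np.unique(labels)) < 2:
            rows.append({"structure": "_".join(pred.structure_key), "auc": np.nan, "ba": np.nan})
            continue
        m = confusion_metrics(scores, labels, threshold)
        rows.append({"structure": "_".join(pred.structure_key), "auc": m.auc, "ba": m.ba})
    per_structure = pd.DataFrame(rows)
    pooled = confusion_metrics(np.concatenate(all_scores), np.concatenate(all_labels), threshold)
    return {
        "per_structure": per_structure,
        "pooled": pooled,
        "mean_structure_auc": float(per_structure["auc"].mean(skipna=True)),
        "pooling": pooling,
    }
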