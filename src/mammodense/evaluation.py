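"""Evaluation metrics for multi-annotator segmentation.

Without a unique ground truth, predictions are scored against each expert
independently, against the experts' pixel-wise AND, and against the closest
expert per sample (the primary statistic).  Percent-density agreement is
summarized by the Pearson coefficient, and the spread between the predicted
and annotated mask distributions by a generalized energy distance built
from pairwise 1 - Dice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (AnnotatorCountMismatch, DegenerateVariance,
                     InsufficientSamples, MammodenseError, ShapeMismatch)

__all__ = ["dice", "closest_annotator_dice", "and_fusion", "percent_success",
           "pd_correlation", "ged", "EvalRecord", "evaluate_records",
           "aggregate_records"]


def dice(m1: np.ndarray, m2: np.ndarray) -> float:
    """Sørensen–Dice overlap ``2|M1 ∩ M2| / (|M1| + |M2|)``.

    Two empty masks agree perfectly (1.0); empty vs nonempty scores 0."""
    m1 = np.asarray(m1, dtype=bool)
    m2 = np.asarray(m2, dtype=bool)
    if m1.shape != m2.shape:
        raise ShapeMismatch(f"{m1.shape} vs {m2.shape}")
    denom = int(m1.sum()) + int(m2.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((m1 & m2).sum()) / denom


def closest_annotator_dice(pred: np.ndarray,
                           annotations: Sequence[np.ndarray]) -> float:
    """Max over annotators of ``dice(pred, annotation)``."""
    if not len(annotations):
        raise AnnotatorCountMismatch("need at least one annotation")
    return max(dice(pred, a) for a in annotations)


def and_fusion(annotations: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise intersection of all annotators' masks."""
    if len(annotations) < 2:
        raise AnnotatorCountMismatch("AND fusion needs >= 2 annotators")
    return np.logical_and.reduce([np.asarray(a, bool) for a in annotations])


@dataclass
class EvalRecord:
    sample_id: str
    dice_vs_each_annotator: list[float]
    dice_vs_and: float
    dice_closest: float
    pd_model: float
    pd_annotators: list[float]
    center_id: str = ""
    dice_vs_truth: float | None = None


def percent_success(records: Sequence[EvalRecord], threshold: float) -> float:
    """Percentage of samples whose closest-annotator Dice exceeds the
    inter-annotator concordance ``threshold``."""
    if not len(records):
        raise MammodenseError("no records")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    wins = sum(r.dice_closest > threshold for r in records)
    return 100.0 * wins / len(records)


def pd_correlation(pd_model: Sequence[float], pd_annotator: Sequence[float]) -> float:
    """Pearson product-moment correlation of percent densities."""
    a = np.asarray(pd_model, dtype=float)
    b = np.asarray(pd_annotator, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ShapeMismatch("need two equal-length series of >= 3 values")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise DegenerateVariance("constant series")
    return float(stats.pearsonr(a, b).statistic)


def ged(predictions: Sequence[np.ndarray],
        annotations: Sequence[np.ndarray]) -> float:
    """Squared generalized energy distance between the sets of predicted and
    annotated masks, with distance ``d = 1 - Dice``:

        GED^2 = 2 E[d(s, y)] - E[d(s, s')] - E[d(y, y')]

    with expectations over all (ordered) pairs from the provided sets.
    Coincident distributions give 0."""
    if len(predictions) < 1 or len(annotations) < 2:
        raise InsufficientSamples("need >= 1 prediction and >= 2 annotations")
    d = lambda a, b: 1.0 - dice(a, b)
    cross = np.mean([d(s, y) for s in predictions for y in annotations])
    within_s = np.mean([d(s, s2) for s in predictions for s2 in predictions])
    within_y = np.mean([d(y, y2) for y in annotations for y2 in annotations])
    return float(2.0 * cross - within_s - within_y)


def evaluate_records(samples, preds, breasts=None) -> list[EvalRecord]:
    """Build one :class:`EvalRecord` per (sample, predicted mask) pair.

    ``samples`` are :class:`~mammodense.training.Sample` objects; percent
    densities use each sample's breast mask."""
    records = []
    for s, pred in zip(samples, preds):
        pred = np.asarray(pred, bool)
        n_breast = max(int(s.breast.sum()), 1)
        rec = EvalRecord(
            sample_id=s.sample_id,
            dice_vs_each_annotator=[dice(pred, a) for a in s.annotations],
            dice_vs_and=(dice(pred, and_fusion(s.annotations))
                         if len(s.annotations) >= 2 else float("nan")),
            dice_closest=closest_annotator_dice(pred, s.annotations),
            pd_model=float((pred & s.breast).sum()) / n_breast,
            pd_annotators=[float((np.asarray(a, bool) & s.breast).sum()) / n_breast
                           for a in s.annotations],
            center_id=s.center_id,
            dice_vs_truth=(None if s.true_dense is None
                           else dice(pred, s.true_dense)),
        )
        records.append(rec)
    return records


def aggregate_records(records: Sequence[EvalRecord]) -> dict:
    """Mean ± SD per metric, overall and per center."""
    df = pd.DataFrame([{
        "sample_id": r.sample_id, "center_id": r.center_id,
        "dice_closest": r.dice_closest, "dice_vs_and": r.dice_vs_and,
        "pd_model": r.pd_model,
        **{f"dice_r{i+1}": v for i, v in enumerate(r.dice_vs_each_annotator)},
        **{f"pd_r{i+1}": v for i, v in enumerate(r.pd_annotators)},
    } for r in records])
    numeric = df.drop(columns=["sample_id", "center_id"])
    out = {"overall": {c: {"mean": float(numeric[c].mean()),
                           "sd": float(numeric[c].std(ddof=1))}
                       for c in numeric.columns}}
    if df["center_id"].nunique() > 1:
        out["per_center"] = {
            str(cid): {c: {"mean": float(g[c].mean()),
                           "sd": float(g[c].std(ddof=1))}
                       for c in numeric.columns}
            for cid, g in df.groupby("center_id")}
    return out
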