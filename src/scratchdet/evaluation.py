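"""Frame-level evaluation of predicted scratch tracks against reference.

Scratching frames are the positive class.  Recall is correctly predicted
scratching frames over reference scratching frames; precision is over all
predicted scratching frames; F1 = 2*recall*precision / (recall +
precision); accuracy counts both classes.  Undefined ratios (empty
denominators) are reported as NaN with an explicit flag rather than
silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import FrameLabelTrack, TrainAnnotation

__all__ = ["MetricsReport", "frame_metrics", "f1_score", "cohort_comparison",
           "pooled_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    recall: float
    precision: float
    f1: float
    accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int
    total_scratch_frames_ref: int
    total_scratch_frames_pred: int
    discrepancy: float  # signed (pred - ref) / ref
    undefined: tuple[str, ...] = ()

    @property
    def n_frames(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "recall": self.recall, "precision": self.precision,
            "f1": self.f1, "accuracy": self.accuracy,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "total_scratch_frames_ref": self.total_scratch_frames_ref,
            "total_scratch_frames_pred": self.total_scratch_frames_pred,
            "discrepancy": self.discrepancy,
            "undefined": list(self.undefined),
        }


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean 2*r*p / (r + p); NaN if both inputs are 0."""
    for name, v in (("recall", recall), ("precision", precision)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if recall + precision == 0.0:
        return math.nan
    return 2.0 * recall * precision / (recall + precision)


def _metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> MetricsReport:
    undefined = []
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall = math.nan
        undefined.append("recall")
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = math.nan
        undefined.append("precision")
    if math.isnan(recall) or math.isnan(precision) or recall + precision == 0:
        f1 = math.nan
        undefined.append("f1")
    else:
        f1 = f1_score(recall, precision)
    n = tp + fp + fn + tn
    ref_total = tp + fn
    pred_total = tp + fp
    if ref_total > 0:
        discrepancy = (pred_total - ref_total) / ref_total
    else:
        discrepancy = math.nan
        undefined.append("discrepancy")
    return MetricsReport(
        recall=recall, precision=precision, f1=f1,
        accuracy=(tp + tn) / n if n else math.nan,
        tp=tp, fp=fp, fn=fn, tn=tn,
        total_scratch_frames_ref=ref_total,
        total_scratch_frames_pred=pred_total,
        discrepancy=discrepancy,
        undefined=tuple(undefined),
    )


def frame_metrics(pred: FrameLabelTrack, ref: FrameLabelTrack) -> MetricsReport:
    """Confusion counts and derived metrics over the frames of one video."""
    if pred.n_frames != ref.n_frames:
        raise ValueError(
            f"length mismatch: pred {pred.n_frames} vs ref {ref.n_frames}"
        )
    p = pred.labels.astype(bool)
    r = ref.labels.astype(bool)
    tp = int((p & r).sum())
    fp = int((p & ~r).sum())
    fn = int((~p & r).sum())
    tn = int((~p & ~r).sum())
    return _metrics_from_counts(tp, fp, fn, tn)


def pooled_metrics(
    preds: list[FrameLabelTrack], refs: list[FrameLabelTrack]
) -> MetricsReport:
    """Metrics over the concatenated frames of several videos (frame-pooled,
    as opposed to averaging per-video metrics)."""
    if len(preds) != len(refs) or not preds:
        raise ValueError("need equal-length, non-empty track lists")
    reports = [frame_metrics(p, r) for p, r in zip(preds, refs)]
    return _metrics_from_counts(
        sum(m.tp for m in reports), sum(m.fp for m in reports),
        sum(m.fn for m in reports), sum(m.tn for m in reports),
    )


def cohort_comparison(
    preds: list[TrainAnnotation], refs: list[TrainAnnotation]
) -> dict:
    """Compare total scratching time per video between two annotation sets.

    Returns a per-video table (totals and the prediction normalised to the
    reference as 100%), the Pearson correlation across videos (both r and
    r^2), and the mean absolute percent discrepancy.  Correlation over a
    single video is flagged undefined.
    """
    if len(preds) != len(refs) or not preds:
        raise ValueError("need matched, non-empty annotation lists")
    for p, r in zip(preds, refs):
        if p.video_id != r.video_id:
            raise ValueError(
                f"video lists are not matched: {p.video_id!r} vs {r.video_id!r}"
            )
    pred_tot = np.array([a.total_scratch_frames for a in preds], dtype=float)
    ref_tot = np.array([a.total_scratch_frames for a in refs], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(ref_tot > 0, pred_tot / ref_tot * 100.0, np.nan)
    table = pd.DataFrame(
        {"video_id": [a.video_id for a in refs],
         "pred_frames": pred_tot.astype(int),
         "ref_frames": ref_tot.astype(int),
         "pred_percent_of_ref": normalized}
    )
    undefined: list[str] = []
    if len(preds) >= 2 and np.std(pred_tot) > 0 and np.std(ref_tot) > 0:
        r_val = float(stats.pearsonr(pred_tot, ref_tot).statistic)
    else:
        r_val = math.nan
        undefined.append("pearson_r")
    valid = ~np.isnan(normalized)
    mean_abs = (
        float(np.abs(normalized[valid] - 100.0).mean()) if valid.any() else math.nan
    )
    return {
        "per_video": table,
        "pearson_r": r_val,
        "pearson_r2": r_val**2 if not math.isnan(r_val) else math.nan,
        "mean_abs_discrepancy_percent": mean_abs,
        "undefined": undefined,
    }
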