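"""Threshold-sweep evaluation of saliency maps against ground truth.

A saliency map on the 0-255 scale is binarized at every integer threshold
(mask = saliency >= t, so t = 0 is the all-positive anchor).  Confusion
counts against the whole-tumour mask give precision, recall (= TPR) and FPR
per threshold; ROC and precision-recall areas are computed by trapezoidal
integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .saliency_core import SaliencyMap
from .volume_io import LabelVolume

N_LEVELS = 256


@dataclass(frozen=True)
class ThresholdCurve:
    """Per-threshold confusion counts and derived PR/ROC points."""

    thresholds: np.ndarray  # (256,) ints
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def precision(self) -> np.ndarray:
        """TP / (TP + FP); defined as 1 where no voxel is predicted positive."""
        denom = self.tp + self.fp
        out = np.ones(len(self.thresholds))
        nz = denom > 0
        out[nz] = self.tp[nz] / denom[nz]
        return out

    @property
    def recall(self) -> np.ndarray:
        """TP / (TP + FN), the true-positive rate."""
        return self.tp / (self.tp + self.fn)

    tpr = recall

    @property
    def fpr(self) -> np.ndarray:
        return self.fp / (self.fp + self.tn)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "TP": self.tp,
                "FP": self.fp,
                "TN": self.tn,
                "FN": self.fn,
                "precision": self.precision,
                "recall": self.recall,
                "FPR": self.fpr,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class EvalSummary:
    """Area-under-curve summary for one subject."""

    auc_roc: float
    auc_pr: float
    subject_id: str = ""


def threshold_mask(saliency: SaliencyMap | np.ndarray, t: int) -> np.ndarray:
    """Binarize the map at threshold ``t`` (inclusive): mask = saliency >= t."""
    if not 0 <= t <= 255:
        raise ValidationError(f"threshold must be in [0, 255], got {t}")
    data = np.asarray(getattr(saliency, "data", saliency))
    return data >= t


def sweep_curve(saliency: SaliencyMap | np.ndarray, gt: LabelVolume | np.ndarray) -> ThresholdCurve:
    """Confusion counts of the map against ground truth at all 256 thresholds.

    The positive class is the whole-tumour mask (any nonzero label); counts
    at every threshold partition the full voxel set.
    """
    data = np.asarray(getattr(saliency, "data", saliency))
    labels = np.asarray(getattr(gt, "data", gt))
    if data.shape != labels.shape:
        raise ValidationError(f"map shape {data.shape} != ground truth shape {labels.shape}")
    positive = labels > 0
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0:
        raise ValidationError("ground truth contains no tumour voxels; recall is undefined")

    thresholds = np.arange(N_LEVELS)
    pos_vals = np.sort(data[positive].ravel())
    neg_vals = np.sort(data[~positive].ravel())
    # voxels >= t  ==  total - (# voxels strictly below t)
    tp = n_pos - np.searchsorted(pos_vals, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_vals, thresholds, side="left")
    return ThresholdCurve(
        thresholds=thresholds,
        tp=tp.astype(np.int64),
        fp=fp.astype(np.int64),
        tn=(n_neg - fp).astype(np.int64),
        fn=(n_pos - tp).astype(np.int64),
    )


def auc(curve: ThresholdCurve, subject_id: str = "") -> EvalSummary:
    """Trapezoidal areas under the ROC and precision-recall curves.

    ROC points are sorted by FPR with anchors (0, 0) and (1, 1) appended; the
    PR area is integrated over recall with the curve's own endpoints.
    """
    fpr = np.concatenate([[0.0], curve.fpr, [1.0]])
    tpr = np.concatenate([[0.0], curve.tpr, [1.0]])
    order = np.lexsort((tpr, fpr))
    auc_roc = float(np.trapezoid(tpr[order], fpr[order]))

    # traverse thresholds descending so recall is non-decreasing and ties at
    # equal recall are entered at the highest-precision point, with the
    # conventional (recall=0, precision=1) anchor
    rec = np.concatenate([[0.0], curve.recall[::-1]])
    prec = np.concatenate([[1.0], curve.precision[::-1]])
    auc_pr = float(np.trapezoid(prec, rec))
    return EvalSummary(auc_roc=auc_roc, auc_pr=auc_pr, subject_id=subject_id)


def summary_frame(summaries: list[EvalSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in summaries],
            "auc_roc": [s.auc_roc for s in summaries],
            "auc_pr": [s.auc_pr for s in summaries],
        }
    )
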