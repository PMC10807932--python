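"""Segmentation evaluation metrics: DSC, precision, recall, MSD.

DSC = 2 TP / (2 TP + FP + FN); precision = TP / (TP + FP);
recall = TP / (TP + FN).  MSD is the symmetric mean of nearest-point
distances between the two surfaces extracted by marching cubes:

    MSD = ( sum_i d(p_i, S') + sum_j d(p'_j, S) ) / (n_S + n_S')

When both masks are empty, overlap metrics are defined as 1.0 (perfect
agreement on nothing); MSD on an empty surface is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .volume import LabelMap

__all__ = ["SegMetrics", "dsc", "precision", "recall", "msd", "evaluate_masks"]


@dataclass
class SegMetrics:
    dsc: float
    precision: float
    recall: float
    msd_mm: float
    tp: int
    fp: int
    fn: int


def _counts(pred: LabelMap, ref: LabelMap) -> tuple[int, int, int]:
    pred.check_same_grid(ref, "prediction and reference")
    p = pred.data > 0
    r = ref.data > 0
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    return tp, fp, fn


def dsc(pred: LabelMap, ref: LabelMap) -> float:
    tp, fp, fn = _counts(pred, ref)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def precision(pred: LabelMap, ref: LabelMap) -> float:
    tp, fp, _ = _counts(pred, ref)
    return 1.0 if tp + fp == 0 else tp / (tp + fp)


def recall(pred: LabelMap, ref: LabelMap) -> float:
    tp, _, fn = _counts(pred, ref)
    return 1.0 if tp + fn == 0 else tp / (tp + fn)


def _surface_points(mask: LabelMap) -> np.ndarray:
    data = mask.data.astype(float)
    if not np.any(data > 0):
        raise ValueError("empty mask has no surface")
    padded = np.pad(data, 1)  # so surfaces close at the grid boundary
    verts, *_ = marching_cubes(padded, level=0.5, spacing=tuple(mask.spacing))
    return verts - mask.spacing  # undo the one-voxel pad offset


def msd(pred: LabelMap, ref: LabelMap) -> float:
    """Symmetric mean surface distance (mm) between marching-cubes surfaces."""
    pred.check_same_grid(ref, "prediction and reference")
    sp = _surface_points(pred)
    sr = _surface_points(ref)
    d_pr = cKDTree(sr).query(sp, k=1)[0]
    d_rp = cKDTree(sp).query(sr, k=1)[0]
    return float((d_pr.sum() + d_rp.sum()) / (len(sp) + len(sr)))


def evaluate_masks(pred: LabelMap, ref: LabelMap) -> SegMetrics:
    tp, fp, fn = _counts(pred, ref)
    both_empty = (tp + fp + fn) == 0
    return SegMetrics(
        dsc=dsc(pred, ref),
        precision=precision(pred, ref),
        recall=recall(pred, ref),
        msd_mm=0.0 if both_empty else msd(pred, ref),
        tp=tp, fp=fp, fn=fn,
    )
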