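"""Scoring of pipeline output against simulator ground truth.

These helpers never feed back into the pipeline; they only measure how well
segmentation, tracking and classification recover what the simulator logged.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .images import LabelMap

__all__ = ["overlap_counts", "iou_matrix", "match_labels", "segmentation_score"]


def overlap_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Joint pixel-count histogram of two label arrays (index [la, lb])."""
    if a.shape != b.shape:
        raise ValueError("label arrays differ in shape")
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    idx = a.astype(np.int64) * nb + b.astype(np.int64)
    return np.bincount(idx.ravel(), minlength=na * nb).reshape(na, nb)


def iou_matrix(seg: LabelMap, truth: LabelMap) -> np.ndarray:
    """IoU of every (segmented, truth) label pair; row/col 0 are background."""
    counts = overlap_counts(seg.labels, truth.labels)
    area_a = counts.sum(axis=1, keepdims=True)
    area_b = counts.sum(axis=0, keepdims=True)
    union = area_a + area_b - counts
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, counts / union, 0.0)
    iou[0, :] = 0.0
    iou[:, 0] = 0.0
    return iou


def match_labels(
    seg: LabelMap, truth: LabelMap, min_iou: float = 0.0
) -> dict[int, tuple[int, float]]:
    """Optimal one-to-one assignment seg label -> (truth label, IoU).

    Maximum-weight bipartite matching on IoU; pairs below ``min_iou`` are
    dropped from the result.
    """
    iou = iou_matrix(seg, truth)
    rows, cols = linear_sum_assignment(-iou)
    out = {}
    for r, c in zip(rows, cols):
        if r == 0 or c == 0:
            continue
        if iou[r, c] > max(min_iou, 0.0):
            out[int(r)] = (int(c), float(iou[r, c]))
    return out


def segmentation_score(
    seg: LabelMap, truth: LabelMap, min_iou: float = 0.7
) -> dict:
    """Fraction of truth cells matched one-to-one at IoU >= ``min_iou``."""
    matches = match_labels(seg, truth, min_iou=min_iou)
    n_truth = len(truth.label_ids())
    n_seg = len(seg.label_ids())
    return {
        "n_truth": n_truth,
        "n_seg": n_seg,
        "n_matched": len(matches),
        "match_rate": len(matches) / n_truth if n_truth else float("nan"),
        "mean_iou": float(np.mean([v[1] for v in matches.values()]))
        if matches
        else float("nan"),
    }
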