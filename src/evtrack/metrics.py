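"""Segmentation evaluation helpers: label-permutation equality, instance
F1 at an IoU threshold, and foreground pixel accuracy."""

from __future__ import annotations

import numpy as np


def masks_equal_up_to_permutation(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff the two label images induce the same partition of the pixels
    into background and instances (labels may be permuted)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a > 0, b > 0):
        return False
    # each a-instance must map onto exactly one b-instance and vice versa
    fg = a > 0
    pairs = np.unique(np.stack([a[fg], b[fg]]), axis=1)
    return (np.unique(pairs[0]).size == pairs.shape[1]
            and np.unique(pairs[1]).size == pairs.shape[1])


def _iou_matrix(gt: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    gt_ids = np.unique(gt)
    gt_ids = gt_ids[gt_ids > 0]
    pr_ids = np.unique(pred)
    pr_ids = pr_ids[pr_ids > 0]
    iou = np.zeros((gt_ids.size, pr_ids.size))
    for i, g in enumerate(gt_ids):
        gmask = gt == g
        garea = gmask.sum()
        for j, p in enumerate(pr_ids):
            inter = (pred[gmask] == p).sum()
            if inter:
                union = garea + (pred == p).sum() - inter
                iou[i, j] = inter / union
    return iou, gt_ids, pr_ids


def instance_f1(gt: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.5) -> float:
    """Instance-level F1: greedy one-to-one matching at the IoU threshold."""
    iou, gt_ids, pr_ids = _iou_matrix(gt, pred)
    if gt_ids.size == 0 and pr_ids.size == 0:
        return 1.0
    if gt_ids.size == 0 or pr_ids.size == 0:
        return 0.0
    matched = 0
    used_g, used_p = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(iou, axis=None)[::-1], iou.shape))[0]
    for i, j in order:
        if iou[i, j] < iou_threshold:
            break
        if i in used_g or j in used_p:
            continue
        used_g.add(i)
        used_p.add(j)
        matched += 1
    precision = matched / pr_ids.size
    recall = matched / gt_ids.size
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def pixel_accuracy(gt_fg: np.ndarray, pred_fg: np.ndarray) -> float:
    """Binary foreground/background pixel accuracy."""
    gt_fg = np.asarray(gt_fg, dtype=bool)
    pred_fg = np.asarray(pred_fg, dtype=bool)
    return float((gt_fg == pred_fg).mean())
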