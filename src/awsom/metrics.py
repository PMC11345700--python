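"""Evaluation metrics against ground truth: confusion counts, spatial
accuracy (Sørensen–Dice × 100), BOLD sensitivity (recall × 100) and signal
integrity (Pearson correlation × 100 between the ground-truth magnitude map
and the significance-masked COPE)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GridError
from .phantom import ROAMask

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "spatial_accuracy",
    "bold_sensitivity",
    "signal_integrity",
    "per_mask_report",
    "reports_to_frame",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_truth(self) -> int:
        return self.tp + self.fn

    @property
    def n_detected(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """SA/BS/SI for one evaluation scope (a single mask or the whole brain)."""

    scope: str
    sa: float
    bs: float
    si: float
    counts: ConfusionCounts


def confusion(detected: np.ndarray, truth: np.ndarray, brain_mask: np.ndarray) -> ConfusionCounts:
    """TP/FP/FN/TN counts restricted to the brain mask."""
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not detected.shape == truth.shape == brain_mask.shape:
        raise GridError("detected, truth and brain mask grids differ")
    if np.any(truth & ~brain_mask):
        raise GridError("ground truth extends outside the brain mask")
    d = detected & brain_mask
    return ConfusionCounts(
        tp=int((d & truth).sum()),
        fp=int((d & ~truth).sum()),
        fn=int((~d & truth & brain_mask).sum()),
        tn=int((~d & ~truth & brain_mask).sum()),
    )


def spatial_accuracy(c: ConfusionCounts) -> float:
    """Sørensen–Dice coefficient in percent: 100 * 2TP / (2TP + FN + FP)."""
    if c.n_truth == 0:
        raise ValueError("spatial accuracy undefined for empty ground truth")
    return 100.0 * 2.0 * c.tp / (2.0 * c.tp + c.fn + c.fp)


def bold_sensitivity(c: ConfusionCounts) -> float:
    """Recall in percent: 100 * TP / (TP + FN)."""
    if c.n_truth == 0:
        raise ValueError("sensitivity undefined for empty ground truth")
    return 100.0 * c.tp / (c.tp + c.fn)


def signal_integrity(
    gt_map: np.ndarray,
    cope: np.ndarray,
    sig: np.ndarray,
    brain_mask: np.ndarray,
) -> float:
    """Correlation (× 100) between ground-truth magnitudes and masked COPEs.

    The Pearson correlation is taken over *all* brain-mask voxels between
    the ground-truth magnitude map and ``cope * sig`` — voxels outside the
    ROA and undetected voxels enter as zeros, so misses and false positives
    both degrade the score.  Returns 0 when nothing was detected or either
    field is constant.
    """
    if not gt_map.shape == cope.shape == sig.shape == brain_mask.shape:
        raise GridError("grids differ")
    m = np.asarray(brain_mask, dtype=bool)
    sig = np.asarray(sig, dtype=bool)
    if not (sig & m).any():
        return 0.0
    a = np.asarray(gt_map, dtype=float)[m]
    b = (np.where(sig, cope, 0.0))[m]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return 100.0 * float(np.corrcoef(a, b)[0, 1])


def _assign_fp_to_masks(
    detected: np.ndarray, masks: list[ROAMask], union: np.ndarray, brain_mask: np.ndarray
) -> dict[int, int]:
    """Count false positives per mask, attributed to the nearest centroid.

    Ties break toward the lower mask label.
    """
    fp_vox = np.argwhere(detected & brain_mask & ~union)
    counts = {m.label: 0 for m in masks}
    if fp_vox.size == 0:
        return counts
    cents = np.stack([m.centroid() for m in masks])  # (4, 3)
    d2 = ((fp_vox[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)  # argmin takes the first (lowest label) on ties
    for i, m in enumerate(masks):
        counts[m.label] = int((nearest == i).sum())
    return counts


def per_mask_report(
    detected: np.ndarray,
    masks: list[ROAMask],
    brain_mask: np.ndarray,
    cope: np.ndarray | None = None,
) -> list[MetricsReport]:
    """SA/BS/SI per ROA mask plus the whole brain.

    Per-mask TP/FN come from that mask's own voxels; false positives
    (detections outside every mask) are attributed to the nearest mask
    centroid so that whole-brain counts equal the sum over masks.  Signal
    integrity uses each mask's magnitude map against the COPE masked to the
    detections assigned to that mask; it requires ``cope`` (else reported
    as NaN).
    """
    detected = np.asarray(detected, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    shape = brain_mask.shape
    dense = [m.to_dense(shape) for m in masks]
    union = np.zeros(shape, dtype=bool)
    for d in dense:
        if (union & d).any():
            raise GridError("ROA masks overlap")
        union |= d
    fp_counts = _assign_fp_to_masks(detected, masks, union, brain_mask)

    fp_vox = np.argwhere(detected & brain_mask & ~union)
    cents = np.stack([m.centroid() for m in masks])
    nearest = (
        np.argmin(((fp_vox[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2), axis=1)
        if fp_vox.size else np.empty(0, dtype=int)
    )

    reports = []
    n_brain = int(brain_mask.sum())
    for i, (m, dm) in enumerate(zip(masks, dense)):
        tp = int((detected & dm).sum())
        fn = int(m.n_voxels - tp)
        fp = fp_counts[m.label]
        tn = n_brain - tp - fn - fp
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        if cope is not None and m.magnitude_pct is not None:
            assigned = detected & dm
            if fp_vox.size:
                sel = fp_vox[nearest == i]
                assigned = assigned.copy()
                assigned[tuple(sel.T)] = True
            si = signal_integrity(m.magnitude_map(shape), cope, assigned, brain_mask)
        else:
            si = float("nan")
        reports.append(MetricsReport(
            scope=f"mask_{m.label}", sa=spatial_accuracy(c), bs=bold_sensitivity(c),
            si=si, counts=c,
        ))

    c_all = confusion(detected, union, brain_mask)
    if cope is not None and masks[0].magnitude_pct is not None:
        gt = np.zeros(shape)
        for m in masks:
            gt += m.magnitude_map(shape)
        si_all = signal_integrity(gt, cope, detected, brain_mask)
    else:
        si_all = float("nan")
    reports.append(MetricsReport(
        scope="whole_brain", sa=spatial_accuracy(c_all), bs=bold_sensitivity(c_all),
        si=si_all, counts=c_all,
    ))
    return reports


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    """Tidy one-row-per-scope frame (scope, sa, bs, si, tp, fp, fn, tn)."""
    return pd.DataFrame(
        [dict(scope=r.scope, sa=r.sa, bs=r.bs, si=r.si,
              tp=r.counts.tp, fp=r.counts.fp, fn=r.counts.fn, tn=r.counts.tn)
         for r in reports]
    )
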