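"""Segment-level agreement metrics between two binary artifact annotations.

Predicted and reference annotations are compared on the 2x2 segment
confusion matrix; sensitivity, specificity, accuracy and Cohen's kappa
are derived from the counts.  When stage labels are available the
comparison is restricted to NREM and REM segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import NREM_STAGES, REM_STAGES, stage_of_segment


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    predicted: np.ndarray,
    truth: np.ndarray,
    restrict: np.ndarray | None = None,
) -> ConfusionCounts:
    """Count the 2x2 table over (optionally restricted) segments."""
    pred = np.asarray(predicted, dtype=bool)
    ref = np.asarray(truth, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError("predicted and truth masks differ in length")
    keep = np.ones_like(pred) if restrict is None else np.asarray(restrict, dtype=bool)
    pred, ref = pred[keep], ref[keep]
    return ConfusionCounts(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
        tn=int(np.sum(~pred & ~ref)),
    )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and Cohen's kappa from counts.

    Cohen's kappa is (p_o - p_e) / (1 - p_e) with expected agreement
    p_e computed from the marginal totals of the 2x2 table.
    """
    n = c.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    po = (c.tp + c.tn) / n
    pe = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / n**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": po,
        "kappa": kappa,
    }


def nrem_rem_mask(stage_labels, n_segments: int) -> np.ndarray:
    """Boolean mask of segments scored as NREM or REM sleep."""
    seg_stage = stage_of_segment(stage_labels, n_segments)
    pool = NREM_STAGES | REM_STAGES
    return np.array([s in pool for s in seg_stage])
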