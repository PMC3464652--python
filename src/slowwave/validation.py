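"""Scoring detected marks against generator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EventMarks
from .synthgen import GroundTruth


@dataclass
class DetectionScore:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity_pct(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def false_positive_rate_pct(self) -> float:
        """FP / (TP + FP), as a percentage of all detections."""
        denom = self.tp + self.fp
        return 100.0 * self.fp / denom if denom else 0.0


def score_detection(truth: GroundTruth, marks: EventMarks, tol_s: float = 0.5) -> DetectionScore:
    """Greedy one-to-one matching of marks to true events within ``tol_s``.

    Each true event can absorb at most one mark; a mark with no unclaimed
    true event within tolerance is a false positive, an unclaimed true
    event a false negative.
    """
    tp = fp = fn = 0
    channels = set(truth.arrivals) | set(marks.by_channel)
    for ch in channels:
        true_t = np.asarray(truth.arrivals.get(ch, ()))
        claimed = np.zeros(len(true_t), dtype=bool)
        for t in marks.times(ch):
            if len(true_t):
                d = np.abs(true_t - t)
                d[claimed] = np.inf
                j = int(np.argmin(d))
                if d[j] <= tol_s:
                    claimed[j] = True
                    tp += 1
                    continue
            fp += 1
        fn += int((~claimed).sum())
    return DetectionScore(tp=tp, fp=fp, fn=fn)
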