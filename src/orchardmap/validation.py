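"""Pixel-level scoring of predicted canopy masks against labeled truth.

Precision = TP / (TP + FP) and F1 = TP / (TP + (FP + FN)/2), counted over
non-nodata pixels.  Sample-based validation mirrors the field protocol of
scoring a handful of manually labeled patches per parcel; the pooled score
micro-averages by summing TP/FP/FN over samples.  Undefined denominators are
flagged (NaN) rather than silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import CanopyMask


@dataclass(frozen=True)
class MaskScore:
    """Pixel confusion counts and the derived precision / recall / F1."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else math.nan

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def f1(self) -> float:
        d = self.tp + (self.fp + self.fn) / 2.0
        return self.tp / d if d else math.nan

    @property
    def precision_defined(self) -> bool:
        return self.tp + self.fp > 0

    @property
    def f1_defined(self) -> bool:
        return self.tp + self.fp + self.fn > 0


def _confusion(pred: np.ndarray, truth: np.ndarray,
               valid: np.ndarray) -> MaskScore:
    p = pred.astype(bool) & valid
    t = truth.astype(bool) & valid
    return MaskScore(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                     fn=int((~p & t).sum()))


def score_segmentation(pred: CanopyMask, truth: CanopyMask) -> MaskScore:
    """Score a predicted canopy mask against a labeled truth mask.

    Pixels flagged nodata in either mask are excluded.  If both masks are
    all-negative the score is returned with NaN precision/F1 (flagged
    undefined) rather than raising.
    """
    if pred.mask.shape != truth.mask.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.mask.shape} vs truth {truth.mask.shape}")
    valid = ~(pred.nodata_mask | truth.nodata_mask)
    return _confusion(pred.mask, truth.mask, valid)


def score_samples(pred: CanopyMask,
                  samples: list[tuple[tuple[int, int, int, int], np.ndarray]]
                  ) -> tuple[list[MaskScore], MaskScore]:
    """Score labeled patches; returns per-sample scores and the micro-pooled score.

    Each sample is ``(window, truth_patch)`` with a half-open window
    ``(r0, r1, c0, c1)`` into the prediction raster and a binary truth patch
    of the window's shape.
    """
    if not samples:
        raise ValueError("empty sample list")
    shape = pred.mask.shape
    scores = []
    for window, patch in samples:
        r0, r1, c0, c1 = window
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise ValueError(f"sample window {window} outside raster {shape}")
        patch = np.asarray(patch)
        if patch.shape != (r1 - r0, c1 - c0):
            raise ValueError(
                f"truth patch shape {patch.shape} does not match window {window}")
        valid = ~pred.nodata_mask[r0:r1, c0:c1]
        scores.append(_confusion(pred.mask[r0:r1, c0:c1], patch, valid))
    pooled = MaskScore(tp=sum(s.tp for s in scores),
                       fp=sum(s.fp for s in scores),
                       fn=sum(s.fn for s in scores))
    return scores, pooled


def scores_to_frame(scores: dict[str, MaskScore]) -> pd.DataFrame:
    """Tabulate named scores with F1/precision columns (plus recall)."""
    rows = [(name, s.f1, s.precision, s.recall, s.tp, s.fp, s.fn)
            for name, s in scores.items()]
    return pd.DataFrame(rows, columns=["parcel", "f1_score", "precision",
                                       "recall", "tp", "fp", "fn"])
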