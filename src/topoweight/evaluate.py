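"""Comparing and aggregating weighting tracks.

The headline statistic is a scaled Euclidean distance between two weighting
vectors,

    d = sqrt( sum_i (w_i - x_i)^2 / m_i^2 / (n - 1) ),    m_i = max(w_i, 1 - w_i),

where w is the reference (true) weighting and x the estimate. Each
coordinate is scaled by its maximum possible deviation, so d runs from 0
(identical) to 1 (maximal discrepancy). Note d is deliberately asymmetric:
the scale factors come from the first argument only.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .treecore import GenealogyError
from .weighting import WeightTrack

__all__ = ["weighting_distance", "average_track", "smooth_track"]


def weighting_distance(
    w_true: Sequence[float], w_est: Sequence[float]
) -> float:
    """Scaled Euclidean distance between two weighting vectors, in [0, 1]."""
    w = np.asarray(w_true, dtype=float)
    x = np.asarray(w_est, dtype=float)
    if w.shape != x.shape:
        raise GenealogyError("weighting vectors differ in length")
    n = w.size
    if n < 2:
        raise GenealogyError("need at least 2 weighting values")
    for v, name in ((w, "w_true"), (x, "w_est")):
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise GenealogyError(f"{name} entries must lie in [0, 1]")
        if abs(v.sum() - 1.0) > 1e-9:
            raise GenealogyError(f"{name} must sum to 1 (got {v.sum()!r})")
    m = np.maximum(w, 1.0 - w)  # never 0 on [0, 1]: max(w, 1-w) >= 0.5
    d = float(np.sqrt(np.sum(((w - x) / m) ** 2) / (n - 1)))
    # the raw formula can exceed 1 by a few percent in contrived corners
    # (several coordinates near their maximal deviation at once); clamp so
    # the statistic honors its advertised 0-1 scale
    return min(d, 1.0)


def average_track(track: WeightTrack, span_weighted: bool = False) -> np.ndarray:
    """Per-topology mean weights over a track; missing rows are skipped.

    With ``span_weighted`` each row is weighted by its interval length
    (needed when rows are true-genealogy blocks of unequal span).
    """
    num = np.zeros(len(track.topologies))
    denom = 0.0
    for interval, rec in track.rows:
        if rec is None:
            continue
        if span_weighted:
            if interval is None:
                raise GenealogyError("span weighting needs row intervals")
            w = float(interval.span)
        else:
            w = 1.0
        num += w * np.asarray(rec.weights)
        denom += w
    if denom == 0:
        raise GenealogyError("no resolved rows to average")
    return num / denom


def smooth_track(track: WeightTrack, window_bp: int) -> list[np.ndarray | None]:
    """Center-weighted moving average of the weights along the genome.

    Each row becomes the mean of all resolved rows (same chromosome) whose
    interval midpoints fall within ``window_bp`` of its own midpoint; row
    count is preserved and smoothed rows still sum to 1. A plain moving
    average stands in for display-oriented loess smoothing.
    """
    if window_bp <= 0:
        raise GenealogyError("window_bp must be positive")
    mids = []
    for interval, _ in track.rows:
        if interval is None:
            raise GenealogyError("smoothing needs row intervals")
        mids.append((interval.chrom, (interval.start + interval.end) / 2.0))
    half = window_bp / 2.0
    out: list[np.ndarray | None] = []
    for i, (interval, rec) in enumerate(track.rows):
        if rec is None:
            out.append(None)
            continue
        chrom, mid = mids[i]
        acc = np.zeros(len(track.topologies))
        count = 0
        for j, (_, other) in enumerate(track.rows):
            if other is None or mids[j][0] != chrom:
                continue
            if abs(mids[j][1] - mid) <= half:
                acc += np.asarray(other.weights)
                count += 1
        out.append(acc / count)
    return out
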