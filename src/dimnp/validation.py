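"""Evaluation machinery: ratio-based manual calling, pooling, ROC, matching.

The "manual" caller flags bases where the occupancy ratio between two samples
leaves the band [0.6, 1/0.6] and segments the flagged runs with the same
length/gap rules as the chi-squared caller. Pairwise manual DNR sets are
pooled by interval union to form a multi-sample reference, against which the
chi-squared track is scored per base by ROC. Agreement between two region
sets is summarised as the matching percentage: the fraction of query regions
whose center lies within a given deviation of the nearest target center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

from .chi2test import LocusTestTrack
from .dnr import DEFAULT_MERGE_GAP, DEFAULT_MIN_LEN, DNR, call_dnrs, filter_and_merge
from .occupancy import OccupancyProfile

__all__ = [
    "MatchingCurve",
    "RocResult",
    "manual_pairwise_dnrs",
    "pool_dnrs",
    "roc_against_reference",
    "mann_whitney_auc",
    "matching_percentage",
]

RATIO_PSEUDOCOUNT = 0.01  # fold-change units; stabilises ratios near zero


@dataclass
class MatchingCurve:
    deviations: np.ndarray
    percentage: np.ndarray  # in [0, 100], non-decreasing


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    thresholds: np.ndarray
    precision_at_cutoff: dict[float, float]


def manual_pairwise_dnrs(
    profile_x: OccupancyProfile,
    profile_y: OccupancyProfile,
    ratio_cutoff: float = 0.6,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
    pseudocount: float = RATIO_PSEUDOCOUNT,
) -> list[tuple[int, int]]:
    """Two-sample ratio caller: flag bases with ratio > 1/cutoff or < cutoff
    (strict), then apply the standard length/gap segmentation.

    A pseudocount keeps the ratio defined at zero occupancy. Swapping x and y
    flags the identical base set (r < c  <=>  1/r > 1/c).
    """
    if len(profile_x) != len(profile_y):
        raise ValueError("profiles must have equal length")
    if not (0 < ratio_cutoff < 1):
        raise ValueError("ratio_cutoff must be in (0, 1)")
    r = (profile_x.values + pseudocount) / (profile_y.values + pseudocount)
    flagged = (r > 1.0 / ratio_cutoff) | (r < ratio_cutoff)
    padded = np.concatenate(([False], flagged, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    runs = list(zip(edges[0::2].tolist(), edges[1::2].tolist()))
    return filter_and_merge(runs, min_len, merge_gap)


def pool_dnrs(dnr_sets: Sequence[Sequence[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Union of interval sets with overlapping or touching intervals
    coalesced; idempotent and order-invariant."""
    all_iv = sorted(iv for s in dnr_sets for iv in s)
    pooled: list[tuple[int, int]] = []
    for s, e in all_iv:
        if pooled and s <= pooled[-1][1]:
            pooled[-1] = (pooled[-1][0], max(pooled[-1][1], e))
        else:
            pooled.append((s, e))
    return pooled


def _interval_mask(intervals: Sequence[tuple[int, int]], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(s, 0) : min(e, length)] = True
    return mask


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the U-statistic identity AUC = U / (n1 * n0), computed from
    midranks; independent of any ROC-curve construction."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_against_reference(
    track: LocusTestTrack,
    reference: Sequence[tuple[int, int]],
    thresholds: Sequence[float] = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7),
) -> RocResult:
    """Per-base ROC of the chi-squared track against reference intervals.

    Truth label of a base = inside/outside the reference; score =
    -log10(P-value); computed over testable bases only. The region-level
    overlap rule is reported alongside as precision at each P cutoff: the
    fraction of regions called at that cutoff that overlap the reference.
    """
    if not reference:
        raise ValueError("reference interval set is empty")
    labels = _interval_mask(reference, len(track))[track.testable]
    scores = -np.log10(track.pvalue[track.testable])
    if labels.all() or not labels.any():
        raise ValueError("reference must leave both positive and negative bases")
    fpr, tpr, _ = roc_curve(labels, scores)
    area = float(_auc(fpr, tpr))

    ref_mask = _interval_mask(reference, len(track))
    precision: dict[float, float] = {}
    for cutoff in thresholds:
        called = call_dnrs(track, cutoff=cutoff)
        if not called:
            precision[cutoff] = float("nan")
            continue
        hit = sum(1 for d in called if ref_mask[d.start : d.end].any())
        precision[cutoff] = hit / len(called)
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=area,
        thresholds=np.asarray(thresholds, dtype=float),
        precision_at_cutoff=precision,
    )


def _centers(intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.array([(s + e) // 2 for s, e in intervals], dtype=float)


def matching_percentage(
    query: Sequence[DNR],
    target: Sequence[tuple[int, int]],
    deviations: Sequence[int] = range(1, 101),
) -> MatchingCurve:
    """Fraction of query regions matched at each deviation.

    A query region is matched at deviation d when the distance between its
    center and the nearest target center is <= d. The curve is non-decreasing
    in d by construction.
    """
    if not len(query):
        raise ValueError("query DNR set is empty")
    devs = np.asarray(list(deviations), dtype=float)
    if not len(target):
        return MatchingCurve(deviations=devs, percentage=np.zeros_like(devs))
    q_centers = np.array([d.center for d in query], dtype=float)
    t_centers = np.sort(_centers(target))
    idx = np.searchsorted(t_centers, q_centers)
    left = t_centers[np.clip(idx - 1, 0, len(t_centers) - 1)]
    right = t_centers[np.clip(idx, 0, len(t_centers) - 1)]
    nearest = np.minimum(np.abs(q_centers - left), np.abs(q_centers - right))
    pct = np.array([100.0 * np.mean(nearest <= d) for d in devs])
    return MatchingCurve(deviations=devs, percentage=pct)
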