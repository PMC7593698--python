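"""Grouping of repetitive intervals by cross-recurrence rate.

Two intervals hold the same underlying conduction pattern when the
rectangular block they span in the recurrence plot is densely recurrent.
The interval similarity matrix of pairwise cross-recurrence rates is
clustered with agglomerative hierarchical clustering (average linkage by
default) and cut at the same RR_min threshold used for detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .detect import RepetitiveInterval
from .recurrence import RecurrencePlot

__all__ = [
    "PatternCluster",
    "cross_rr",
    "interval_similarity",
    "cluster_intervals",
    "filter_clusters",
]


@dataclass(frozen=True)
class PatternCluster:
    """A group of intervals expressing the same repetitive pattern."""

    member_ids: tuple[int, ...]
    intervals: tuple[RepetitiveInterval, ...]
    rank: int = 0

    @property
    def combined_cycles(self) -> float:
        return float(sum(iv.duration_cycles for iv in self.intervals))


def cross_rr(
    rp: RecurrencePlot, a: RepetitiveInterval, b: RepetitiveInterval
) -> float:
    """Cross-recurrence rate per AF cycle between two intervals.

    The recurrence count in the rectangular block rows(a) × columns(b) of
    the plot, excluding main-diagonal cells, normalised as
    count × AFCL / (d_a × d_b).  Symmetric because the plot is.
    """
    n = rp.n
    if not (0 <= a.start < a.end <= n and 0 <= b.start < b.end <= n):
        raise ValueError("interval outside recurrence plot bounds")
    block = rp.recurrent[a.start:a.end, b.start:b.end]
    count = int(block.sum())
    # main-diagonal cells falling inside the block are trivial recurrences
    diag = max(0, min(a.end, b.end) - max(a.start, b.start))
    return (count - diag) * rp.afcl_samples / float(a.duration * b.duration)


def interval_similarity(
    rp: RecurrencePlot, intervals: list[RepetitiveInterval]
) -> np.ndarray:
    """Pairwise cross-recurrence matrix, clipped to [0, 1], self-similarity 1."""
    m = len(intervals)
    sim = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim[j, i] = np.clip(
                cross_rr(rp, intervals[i], intervals[j]), 0.0, 1.0
            )
    return sim


def cluster_intervals(
    sim: np.ndarray,
    intervals: list[RepetitiveInterval],
    rr_min: float = 0.9,
    method: str = "average",
) -> list[PatternCluster]:
    """Cut an agglomerative tree of intervals at distance 1 - rr_min.

    Distance is 1 minus the clipped cross-recurrence similarity; clusters
    are ranked by combined duration (descending).
    """
    m = len(intervals)
    if m == 0:
        raise ValueError("need at least one interval to cluster")
    if m == 1:
        labels = np.array([1])
    else:
        dist = 1.0 - np.clip(sim, 0.0, 1.0)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method=method)
        labels = fcluster(z, t=1.0 - rr_min, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        ids = tuple(int(i) for i in np.flatnonzero(labels == lab))
        clusters.append(PatternCluster(ids, tuple(intervals[i] for i in ids)))
    clusters.sort(key=lambda c: (-c.combined_cycles, c.member_ids))
    return [
        PatternCluster(c.member_ids, c.intervals, rank=r + 1)
        for r, c in enumerate(clusters)
    ]


def filter_clusters(
    clusters: list[PatternCluster], min_cycles: float = 10.0
) -> list[PatternCluster]:
    """Keep clusters whose combined duration exceeds *min_cycles* AF cycles."""
    if min_cycles < 0:
        raise ValueError("min_cycles must be >= 0")
    return [c for c in clusters if c.combined_cycles > min_cycles]


def clusters_to_frame(clusters: list[PatternCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.rank for c in clusters],
            "interval_ids": [";".join(map(str, c.member_ids)) for c in clusters],
            "combined_cycles": [c.combined_cycles for c in clusters],
            "rank": [c.rank for c in clusters],
        }
    )
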