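"""Distance matrix, adaptive threshold, recurrence plot, and erosion.

The distance between two activation-phase snapshots is the mean cosine of
the per-electrode phase differences, mapped back to a fraction of one AF
cycle:

    delta(a, b) = arccos( mean_k cos(phi_a,k - phi_b,k) ) / (2*pi)

so delta = 0 for snapshots completely in phase and delta = 0.5 for
snapshots half a cycle out of phase, and the measure is symmetric.

The recurrence threshold delta_max is adaptive: it is chosen so that the
recurrence rate per AF cycle of the thresholded plot equals a target
RR_max (default 1 — the rate a single pattern repeating for the whole
recording would produce).  Consecutive (thick) recurrences are then
eroded to the single minimum-distance cell of each run, removing false
nearest neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import PhaseSnapshotSeries

__all__ = [
    "DistanceMatrix",
    "RecurrencePlot",
    "snapshot_distance",
    "distance_matrix",
    "adaptive_threshold",
    "threshold_plot",
    "erode",
    "recurrence_rate_per_cycle",
]

_TWO_PI = 2.0 * np.pi


@dataclass
class DistanceMatrix:
    """Symmetric snapshot-distance matrix (float32, values in [0, 0.5]).

    ``snapshot_index`` maps rows back to the original snapshot indices
    when invalid snapshots were dropped.
    """

    values: np.ndarray
    snapshot_index: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class RecurrencePlot:
    """Boolean recurrence indicator over snapshot pairs."""

    recurrent: np.ndarray
    delta_max: float
    rr_max: float
    afcl_samples: int
    eroded: bool = False

    @property
    def n(self) -> int:
        return self.recurrent.shape[0]


def snapshot_distance(
    phase_a: np.ndarray, phase_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Phase distance between two snapshots, as a fraction of one cycle.

    ``mask`` selects the valid electrodes entering the mean; at least one
    must be valid.
    """
    phase_a = np.asarray(phase_a, float)
    phase_b = np.asarray(phase_b, float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase vectors must have the same length")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("no valid electrodes in snapshot pair")
        phase_a, phase_b = phase_a[mask], phase_b[mask]
    c = float(np.mean(np.cos(phase_a - phase_b)))
    return float(np.arccos(np.clip(c, -1.0, 1.0)) / _TWO_PI)


def distance_matrix(phases: PhaseSnapshotSeries) -> DistanceMatrix:
    """All-pairs snapshot distances.

    Electrodes that are invalid for the whole recording are dropped from
    the comparison; snapshots with any remaining invalid electrode are
    excluded (their original indices are kept in ``snapshot_index``).
    Computed via the cosine identity
    mean_k cos(a_k - b_k) = (cos(a)·cos(b) + sin(a)·sin(b)) / K
    so the whole matrix is two rank-K matrix products.
    """
    good_el = phases.valid.any(axis=0)
    if not good_el.any():
        raise ValueError("no valid electrodes in recording")
    valid = phases.valid[:, good_el]
    phase = phases.phase[:, good_el]
    good_snap = valid.all(axis=1)
    if good_snap.sum() < 2:
        raise ValueError("fewer than 2 valid snapshots")
    p = phase[good_snap]
    c, s = np.cos(p), np.sin(p)
    mean_cos = (c @ c.T + s @ s.T) / p.shape[1]
    np.clip(mean_cos, -1.0, 1.0, out=mean_cos)
    d = np.arccos(mean_cos) / _TWO_PI
    d = 0.5 * (d + d.T)  # exact symmetry against float round-off
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d.astype(np.float32), np.flatnonzero(good_snap))


def _eligible_mask(n: int, min_lag: int) -> np.ndarray:
    i, j = np.triu_indices(n, k=max(1, min_lag))
    return i, j


def adaptive_threshold(
    dm: DistanceMatrix,
    afcl_samples: int,
    rr_max: float = 1.0,
    exclude_band: bool = True,
    max_pairs: int = 5_000_000,
    seed: int = 0,
) -> float:
    """Distance threshold delta_max achieving a target recurrence rate.

    The target fraction of recurrent pairs is ``f = min(1, rr_max /
    afcl_samples)``; delta_max is the empirical f-quantile of the eligible
    pairwise distances.  Snapshot pairs closer in time than half a cycle
    are trivially similar, so by default they are excluded from the
    quantile (``exclude_band``).  For very long recordings the quantile is
    estimated from a seeded uniform subsample of at most *max_pairs*
    pairs.
    """
    if afcl_samples < 2:
        raise ValueError("afcl_samples must be >= 2")
    if rr_max <= 0:
        raise ValueError("rr_max must be > 0")
    n = dm.n
    min_lag = int(np.ceil(afcl_samples / 2)) if exclude_band else 1
    i, j = _eligible_mask(n, min_lag)
    if i.size == 0:
        raise ValueError("no eligible snapshot pairs for threshold estimation")
    vals = dm.values[i, j]
    if vals.size > max_pairs:
        rng = np.random.default_rng(seed)
        vals = vals[rng.choice(vals.size, max_pairs, replace=False)]
    f = min(1.0, rr_max / afcl_samples)
    return float(np.quantile(vals, f))


def threshold_plot(
    dm: DistanceMatrix,
    delta_max: float,
    rr_max: float = np.nan,
    afcl_samples: int = 2,
) -> RecurrencePlot:
    """Recurrence at (i, j) iff delta_ij <= delta_max; diagonal true."""
    if not (0.0 <= delta_max <= 0.5):
        raise ValueError("delta_max must be in [0, 0.5]")
    rec = dm.values <= delta_max
    np.fill_diagonal(rec, True)
    return RecurrencePlot(rec, float(delta_max), float(rr_max), int(afcl_samples))


def _erode_rows(rec: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Keep, per row and per maximal run, the min-distance cell.

    Runs may include the main-diagonal cell; its distance is 0, so the
    thick band of trivially similar neighbours around the diagonal (the
    false nearest neighbours) collapses onto the diagonal itself.
    """
    n = rec.shape[0]
    out = np.zeros_like(rec)
    for r in range(n):
        row = rec[r]
        idx = np.flatnonzero(row)
        if idx.size == 0:
            continue
        # maximal runs of consecutive column indices
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(idx)]])
        for s, e in zip(starts, ends):
            run = idx[s:e]
            out[r, run[np.argmin(dist[r, run])]] = True
    return out


def erode(rp: RecurrencePlot, dm: DistanceMatrix) -> RecurrencePlot:
    """Collapse each run of consecutive recurrences to its closest cell.

    A row pass and a column pass each replace every maximal run of
    consecutive recurrences with the single cell of minimum distance; the
    result is their intersection, re-symmetrised by AND with its
    transpose, with the main diagonal restored.  Runs touching the main
    diagonal collapse onto it (self-distance is 0), which removes the
    false-nearest-neighbour band of trivially similar adjacent snapshots.
    Idempotent.
    """
    if rp.eroded:
        raise ValueError("recurrence plot already eroded")
    rows = _erode_rows(rp.recurrent, dm.values)
    cols = _erode_rows(rp.recurrent.T, dm.values.T).T
    rec = rows & cols
    rec &= rec.T
    np.fill_diagonal(rec, True)
    return RecurrencePlot(rec, rp.delta_max, rp.rr_max, rp.afcl_samples, eroded=True)


def recurrence_rate_per_cycle(
    rp: RecurrencePlot, exclude_band: bool = False
) -> float:
    """Off-diagonal recurrence fraction scaled to recurrences per AF cycle.

    A value of 1 means one recurrence per cycle on average — the rate a
    single pattern repeating throughout the recording would produce.  With
    ``exclude_band`` the trivially similar pairs at lag < AFCL/2 are left
    out of both numerator and denominator, matching the pair set used by
    the adaptive threshold.
    """
    n = rp.n
    min_lag = int(np.ceil(rp.afcl_samples / 2)) if exclude_band else 1
    i, j = np.triu_indices(n, k=min_lag)
    if i.size == 0:
        return 0.0
    frac = float(rp.recurrent[i, j].sum()) / i.size
    return frac * rp.afcl_samples
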