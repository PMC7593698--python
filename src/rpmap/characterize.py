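"""Per-pattern summaries: average activation maps, recurrence-distance
heat maps, pattern size, and conduction-direction fields.

The representative snapshot of a pattern is the circular mean of the
phase snapshots at the recurrences on one vertical line of the recurrence
plot inside the interval.  Converting mean phase to time-since-activation
with the AF cycle length gives the average activation-time map (earliest
electrode = 0 ms).  The per-electrode average recurrent phase distance
delta_k^p localises which electrodes actually repeat; the area of
electrodes below the distance threshold (or below a fixed time difference
after scaling by AFCL) is the pattern size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import CycleLengthEstimate, PhaseSnapshotSeries
from .detect import RepetitiveInterval
from .layout import ElectrodeLayout
from .recurrence import RecurrencePlot

__all__ = [
    "PatternSummary",
    "average_pattern",
    "to_activation_map",
    "electrode_distance_map",
    "pattern_size",
    "conduction_direction",
    "summarize",
]

_TWO_PI = 2.0 * np.pi


@dataclass
class PatternSummary:
    """Everything needed to visualise and size one clustered pattern."""

    cluster_id: int
    avg_phase: np.ndarray  # (K,) circular-mean phase per electrode
    activation_map_ms: np.ndarray  # (K,) earliest = 0
    delta_kp: np.ndarray  # (K,) per-electrode recurrent phase distance
    dt_ms: np.ndarray  # (K,) delta_kp converted to time difference
    size_adaptive_cm2: float
    size_fixed_cm2: float
    direction: np.ndarray  # (K, 2) unit vectors; NaN where undefined
    recurrence_times: np.ndarray = field(default_factory=lambda: np.array([], int))


def average_pattern(
    phases: PhaseSnapshotSeries,
    rp: RecurrencePlot,
    interval: RepetitiveInterval,
    snapshot_index: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Circular-mean phase snapshot of a pattern and its recurrence times.

    The reference column is the interval midpoint; the recurrence set is
    that column's (eroded-plot) recurrences inside the interval plus the
    reference itself.  If the midpoint column holds fewer than two
    recurrences, the column with the most recurrences inside the interval
    is used instead.  Per-electrode averaging is circular (angle of the
    summed unit phasors; a zero resultant yields phase 0).

    Returns ``(avg_phase, rows)`` where *rows* are recurrence-plot row
    indices; map them through ``snapshot_index`` for snapshot positions.
    """
    sub = rp.recurrent[interval.start:interval.end, interval.start:interval.end]
    ref = interval.center - interval.start
    col = sub[:, ref]
    if col.sum() < 2:
        counts = sub.sum(axis=0)
        ref = int(np.argmax(counts))
        col = sub[:, ref]
        if col.sum() < 2:
            raise ValueError("no column with >= 2 recurrences inside interval")
    rows = np.flatnonzero(col) + interval.start
    if snapshot_index is None:
        snapshot_index = np.arange(rp.n)
    snap = snapshot_index[rows]
    p = phases.phase[snap]
    z = np.exp(1j * p).mean(axis=0)
    avg = np.angle(z)  # angle(0) == 0: ties resolved toward phase 0
    avg[avg == np.pi] = -np.pi
    return avg, rows


def to_activation_map(avg_phase: np.ndarray, afcl: CycleLengthEstimate) -> np.ndarray:
    """Mean phase → activation time in ms, earliest electrode at 0.

    Phase -pi means "just activated" (time-since-activation 0); phase just
    below pi means a full cycle has nearly elapsed.  Electrodes that
    activated earliest have the largest time-since-activation and are
    assigned activation time 0.
    """
    tau = (np.asarray(avg_phase) + np.pi) / _TWO_PI * afcl.afcl_ms
    return tau.max() - tau


def electrode_distance_map(
    phases: PhaseSnapshotSeries, recurrence_snapshots: np.ndarray
) -> np.ndarray:
    """Average recurrent phase distance delta_k^p per electrode.

    The single-electrode specialisation of the snapshot distance,
    averaged over all unordered pairs of recurrence snapshots:
    mean_{i<j} arccos(cos(phi_k(i) - phi_k(j))) / (2*pi), in [0, 0.5].
    """
    snaps = np.asarray(recurrence_snapshots, int)
    if len(snaps) < 2:
        raise ValueError("need >= 2 recurrence snapshots")
    p = phases.phase[snaps]  # (m, K)
    i, j = np.triu_indices(len(snaps), k=1)
    d = np.arccos(np.clip(np.cos(p[i] - p[j]), -1.0, 1.0)) / _TWO_PI
    return d.mean(axis=0)


def pattern_size(
    delta_kp: np.ndarray,
    layout: ElectrodeLayout,
    afcl: CycleLengthEstimate,
    mode: str = "adaptive",
    delta_max: float | None = None,
    dt_ms: float = 10.0,
) -> float:
    """Area (cm²) of the electrodes participating in the repetitive pattern.

    ``adaptive`` counts electrodes with delta_k^p <= delta_max (the
    adaptive recurrence threshold); ``fixed_dt`` counts electrodes whose
    equivalent time difference delta_k^p × AFCL is below *dt_ms* (default
    10 ms).  Each electrode contributes one spacing² unit cell.
    """
    delta_kp = np.asarray(delta_kp, float)
    if mode == "adaptive":
        if delta_max is None:
            raise ValueError("adaptive mode requires delta_max")
        count = int(np.sum(delta_kp <= delta_max))
    elif mode == "fixed_dt":
        count = int(np.sum(delta_kp * afcl.afcl_ms < dt_ms))
    else:
        raise ValueError(f"unknown size mode {mode!r}")
    return count * layout.spacing**2 / 100.0  # mm² → cm²


def conduction_direction(
    act_map_ms: np.ndarray,
    layout: ElectrodeLayout,
    radius_mm: float | None = None,
    grad_tol: float = 1e-9,
) -> np.ndarray:
    """Local conduction-direction unit vectors from an activation-time map.

    For every electrode, activation time is fitted as a plane over the
    neighbours within *radius_mm* (default 1.5 × spacing, electrode
    included); the direction is the normalised spatial gradient of
    activation time, pointing from early towards late activation — the
    direction of wave-front travel.  Degenerate neighbourhoods (fewer
    than 3 non-collinear sites, or a flat fit) yield NaN.
    """
    if radius_mm is None:
        radius_mm = 1.5 * layout.spacing
    pos = layout.positions
    t = np.asarray(act_map_ms, float)
    out = np.full((layout.n_electrodes, 2), np.nan)
    for k in range(layout.n_electrodes):
        d = np.hypot(pos[:, 0] - pos[k, 0], pos[:, 1] - pos[k, 1])
        nb = np.flatnonzero(d <= radius_mm + 1e-9)
        if len(nb) < 3:
            continue
        a = np.column_stack([np.ones(len(nb)), pos[nb, 0], pos[nb, 1]])
        if np.linalg.matrix_rank(a) < 3:
            continue
        coef, *_ = np.linalg.lstsq(a, t[nb], rcond=None)
        g = coef[1:3]
        norm = np.hypot(*g)
        if norm > grad_tol:
            out[k] = g / norm
    return out


def summarize(
    cluster_id: int,
    phases: PhaseSnapshotSeries,
    rp: RecurrencePlot,
    intervals: list[RepetitiveInterval],
    layout: ElectrodeLayout,
    afcl: CycleLengthEstimate,
    delta_max: float,
    dt_ms: float = 10.0,
    snapshot_index: np.ndarray | None = None,
) -> PatternSummary:
    """Full summary of one cluster, averaged over its longest interval."""
    longest = max(intervals, key=lambda iv: iv.duration)
    avg_phase, rows = average_pattern(phases, rp, longest, snapshot_index)
    if snapshot_index is None:
        snapshot_index = np.arange(rp.n)
    snaps = snapshot_index[rows]
    act_map = to_activation_map(avg_phase, afcl)
    delta_kp = electrode_distance_map(phases, snaps)
    return PatternSummary(
        cluster_id=cluster_id,
        avg_phase=avg_phase,
        activation_map_ms=act_map,
        delta_kp=delta_kp,
        dt_ms=delta_kp * afcl.afcl_ms,
        size_adaptive_cm2=pattern_size(
            delta_kp, layout, afcl, "adaptive", delta_max=delta_max
        ),
        size_fixed_cm2=pattern_size(delta_kp, layout, afcl, "fixed_dt", dt_ms=dt_ms),
        direction=conduction_direction(act_map, layout),
        recurrence_times=snaps,
    )


def summary_to_frame(s: PatternSummary, layout: ElectrodeLayout) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "electrode_id": layout.electrode_id,
            "act_ms": s.activation_map_ms,
            "delta_kp": s.delta_kp,
            "dt_ms": s.dt_ms,
            "dir_x": s.direction[:, 0],
            "dir_y": s.direction[:, 1],
        }
    )
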