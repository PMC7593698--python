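"""Detection of diagonal intervals containing repetitive patterns.

A conduction pattern repeating for several consecutive cycles shows up in
the (eroded) recurrence plot as a square block of diagonal lines around
the main diagonal.  The detector traverses the main diagonal, grows a
square block at every time point, records the longest block whose
recurrence rate per AF cycle stays above RR_min (default 0.9), and takes
local maxima of that duration profile as candidate repetitive intervals.
Candidates overlapping an already accepted, longer interval by more than
50% are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recurrence import RecurrencePlot

__all__ = [
    "RepetitiveInterval",
    "DurationProfile",
    "block_rr",
    "duration_profile",
    "detect_intervals",
]


@dataclass(frozen=True)
class RepetitiveInterval:
    """Half-open snapshot interval [start, end) containing one repetitive pattern."""

    start: int
    end: int
    afcl_samples: int
    rr_per_cycle: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")

    @property
    def duration(self) -> int:
        return self.end - self.start

    @property
    def duration_cycles(self) -> float:
        return self.duration / self.afcl_samples

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "RepetitiveInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class DurationProfile:
    """Per-snapshot longest qualifying block duration D(t) and its RR."""

    duration: np.ndarray  # (N,) snapshots; 0 where no block meets rr_min
    rr: np.ndarray  # block RR per cycle at D(t); 0 where duration is 0
    afcl_samples: int
    rr_min: float


def _integral_image(rec: np.ndarray) -> np.ndarray:
    s = np.zeros((rec.shape[0] + 1, rec.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(rec, axis=0), axis=1, out=s[1:, 1:])
    return s


def _block_count(s: np.ndarray, lo: int, hi: int) -> int:
    """Recurrence count in the square [lo, hi) × [lo, hi) from integral image."""
    return int(s[hi, hi] - 2 * s[lo, hi] + s[lo, lo])


def _block_rr_from_sum(count: int, d: int, afcl: int) -> float:
    # the main diagonal crosses the centred block in d trivially recurrent cells
    return (count - d) * afcl / float(d * d)


def block_rr(rp: RecurrencePlot, center: int, duration: int) -> float:
    """Recurrence rate per AF cycle in a square block centred on the diagonal.

    The d×d block centred at (center, center) is clipped symmetrically at
    the recording edges; recurrences on the main diagonal are excluded
    from the count, which is normalised as count × AFCL / d².
    """
    afcl = rp.afcl_samples
    if duration < 2 * afcl:
        raise ValueError("block duration must be at least 2 AF cycles")
    n = rp.n
    half = duration // 2
    lo = max(0, center - half)
    hi = min(n, center + (duration - half))
    d = hi - lo
    block = rp.recurrent[lo:hi, lo:hi]
    count = int(block.sum())
    return _block_rr_from_sum(count, d, afcl)


def duration_profile(
    rp: RecurrencePlot, rr_min: float = 0.9, step: int | None = None
) -> DurationProfile:
    """Longest block duration with RR per cycle >= rr_min, at every snapshot.

    Blocks grow in increments of *step* (default AFCL/2) from the minimum
    of 2 cycles up to the symmetric edge-clipped maximum 2*min(t, N-t).
    """
    if rr_min <= 0:
        raise ValueError("rr_min must be > 0")
    afcl = rp.afcl_samples
    if step is None:
        step = max(1, afcl // 2)
    n = rp.n
    s = _integral_image(rp.recurrent)
    dur = np.zeros(n, dtype=np.int64)
    rr_at = np.zeros(n, dtype=float)
    d_min = 2 * afcl
    for t in range(n):
        h_max = min(t, n - t)
        if 2 * h_max < d_min:
            continue
        best_d, best_rr = 0, 0.0
        for d in range(d_min, 2 * h_max + 1, step):
            half = d // 2
            lo, hi = t - half, t - half + d
            if lo < 0 or hi > n:
                hi = min(hi, n)
                lo = max(lo, 0)
                d = hi - lo
            rr = _block_rr_from_sum(_block_count(s, lo, hi), d, afcl)
            if rr >= rr_min and d > best_d:
                best_d, best_rr = d, rr
        dur[t] = best_d
        rr_at[t] = best_rr
    return DurationProfile(dur, rr_at, afcl, float(rr_min))


def _plateau_maxima(d: np.ndarray) -> list[int]:
    """Centres (plateau midpoints, rounded down) of local maxima of D(t)."""
    n = len(d)
    centers = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and d[j + 1] == d[i]:
            j += 1
        if d[i] > 0:
            left = d[i - 1] if i > 0 else -1
            right = d[j + 1] if j + 1 < n else -1
            if d[i] > left and d[i] > right:
                centers.append((i + j) // 2)
        i = j + 1
    return centers


def detect_intervals(
    profile: DurationProfile, rr_min: float | None = None, n_snapshots: int | None = None
) -> list[RepetitiveInterval]:
    """Accept non-redundant repetitive intervals from a duration profile.

    Candidates sit at local maxima of D(t) (plateau midpoints) and span
    [t - D/2, t + D/2).  They are resolved greedily by descending
    duration: a candidate overlapping an accepted interval by more than
    50% of the shorter interval's duration is discarded.
    """
    if rr_min is not None and rr_min != profile.rr_min:
        raise ValueError("profile was computed with a different rr_min")
    d = profile.duration
    n = n_snapshots if n_snapshots is not None else len(d)
    candidates = []
    for t in _plateau_maxima(d):
        dur = int(d[t])
        lo = max(0, t - dur // 2)
        hi = min(n, lo + dur)
        lo = max(0, hi - dur)
        candidates.append(
            RepetitiveInterval(lo, hi, profile.afcl_samples, float(profile.rr[t]))
        )
    # longest first; ties broken by earliest start for determinism
    candidates.sort(key=lambda iv: (-iv.duration, iv.start))
    accepted: list[RepetitiveInterval] = []
    for cand in candidates:
        if all(
            cand.overlap(acc) <= 0.5 * min(cand.duration, acc.duration)
            for acc in accepted
        ):
            accepted.append(cand)
    accepted.sort(key=lambda iv: iv.start)
    return accepted
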