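"""Activation annotation, cycle-length estimation, and phase embedding.

Local activation times (LATs) either come in directly (the preferred
input) or are detected from unipolar electrograms with a simple
steepest-negative-slope detector.  LATs are turned into activation-phase
signals in [-pi, pi): a sawtooth that ramps linearly from -pi to pi
between consecutive activations and inverts (wraps pi -> -pi) exactly at
each activation.  Sampling every electrode's phase at a uniform analysis
rate yields the phase-space embedding: each snapshot is a still frame of
the conduction pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "ActivationTimes",
    "CycleLengthEstimate",
    "PhaseSnapshotSeries",
    "detect_activations",
    "estimate_afcl",
    "build_phase",
]

_PI = np.pi
_PHASE_MAX = np.nextafter(np.pi, 0)  # largest representable value < pi


@dataclass
class ActivationTimes:
    """Per-electrode ordered local activation times.

    Attributes
    ----------
    times : list of strictly increasing arrays (ms), one per electrode.
    duration_ms : recording length; all times lie in [0, duration_ms].
    source : "supplied" or "detected".
    """

    times: list[np.ndarray]
    duration_ms: float
    source: str = "supplied"

    def __post_init__(self) -> None:
        self.times = [np.asarray(t, float) for t in self.times]
        for k, t in enumerate(self.times):
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"activation times not strictly increasing (electrode {k})")
            if len(t) and (t[0] < 0 or t[-1] > self.duration_ms):
                raise ValueError(f"activation times outside [0, duration] (electrode {k})")

    @property
    def n_electrodes(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        rows = [(k, t) for k, times in enumerate(self.times) for t in times]
        pd.DataFrame(rows, columns=["electrode_id", "activation_time_ms"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, n_electrodes: int | None = None,
                 duration_ms: float | None = None) -> "ActivationTimes":
        df = pd.read_csv(path)
        if n_electrodes is None:
            n_electrodes = int(df["electrode_id"].max()) + 1
        times = [
            np.sort(df.loc[df["electrode_id"] == k, "activation_time_ms"].to_numpy())
            for k in range(n_electrodes)
        ]
        if duration_ms is None:
            duration_ms = float(df["activation_time_ms"].max()) + 1.0
        return cls(times, duration_ms, source="supplied")


@dataclass(frozen=True)
class CycleLengthEstimate:
    """AF cycle length (AFCL) summary.

    afcl_ms : pooled median inter-activation interval.
    afcl_samples : AFCL expressed in snapshots at the analysis rate.
    iqr_ms : interquartile range of the pooled intervals (dispersion).
    rate_hz : the analysis snapshot rate used for *afcl_samples*.
    """

    afcl_ms: float
    afcl_samples: int
    iqr_ms: float
    rate_hz: float


def detect_activations(
    egm: np.ndarray,
    fs: float,
    refractory_ms: float = 50.0,
    slope_percentile: float = 0.95,
) -> ActivationTimes:
    """Mark LATs at steepest negative deflection slopes.

    A simplified annotator: per electrode, the detection threshold is the
    given percentile of the negative-slope magnitudes; candidate LATs are
    local maxima of negative slope above it, and the refractory period is
    enforced by keeping the steeper of two conflicting detections.

    Defaults (refractory 50 ms, 0.95 percentile) are conservative for
    cycle lengths of 100 ms and above.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if refractory_ms <= 0:
        raise ValueError("refractory_ms must be > 0")
    egm = np.atleast_2d(np.asarray(egm, float))
    duration_ms = egm.shape[1] / fs * 1000.0
    out: list[np.ndarray] = []
    dist = max(1, int(round(refractory_ms * fs / 1000.0)))
    for k, sig in enumerate(egm):
        slope = np.gradient(sig) * fs  # V/s-ish; sign matters, scale does not
        neg = np.clip(-slope, 0.0, None)
        if neg.max() <= 0:
            logger.warning("electrode %d: flat signal, no activations detected", k)
            out.append(np.array([]))
            continue
        thr = np.quantile(neg, slope_percentile)
        if thr <= 0:  # sparse deflections in an otherwise flat trace
            thr = np.quantile(neg[neg > 0], slope_percentile)
        # find_peaks' `distance` keeps the higher (steeper) of close peaks
        peaks, _ = find_peaks(neg, height=thr, distance=dist)
        t = peaks / fs * 1000.0
        out.append(np.clip(t, 0.0, duration_ms))
    return ActivationTimes(out, duration_ms, source="detected")


def estimate_afcl(acts: ActivationTimes, rate_hz: float = 100.0) -> CycleLengthEstimate:
    """Estimate the AF cycle length as the pooled median interval.

    Inter-activation intervals from all electrodes are pooled; AFCL is
    their median and the dispersion their IQR.  Requires at least one
    electrode with two or more activations.
    """
    intervals = np.concatenate(
        [np.diff(t) for t in acts.times if len(t) >= 2] or [np.array([])]
    )
    if intervals.size == 0:
        raise ValueError("no electrode with >= 2 activations; cannot estimate AFCL")
    afcl_ms = float(np.median(intervals))
    q75, q25 = np.percentile(intervals, [75, 25])
    samples = int(round(afcl_ms * rate_hz / 1000.0))
    if samples < 2:
        raise ValueError(
            f"AFCL of {afcl_ms:.1f} ms spans {samples} snapshot(s) at {rate_hz} Hz; "
            "increase the analysis rate"
        )
    return CycleLengthEstimate(afcl_ms, samples, float(q75 - q25), rate_hz)


@dataclass
class PhaseSnapshotSeries:
    """Uniformly sampled activation-phase snapshots.

    Attributes
    ----------
    t_ms : (N,) snapshot times, uniform at *rate_hz*.
    phase : (N, K) matrix of activation phases in [-pi, pi).
    valid : (N, K) boolean mask; False marks electrodes without any
        activation (phase undefined).
    rate_hz : analysis snapshot rate.
    """

    t_ms: np.ndarray
    phase: np.ndarray
    valid: np.ndarray
    rate_hz: float

    @property
    def n_snapshots(self) -> int:
        return self.phase.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.phase.shape[1]


def _electrode_phase(t: np.ndarray, acts: np.ndarray, afcl_ms: float) -> np.ndarray:
    """Sawtooth phase of one electrode on the snapshot grid *t*."""
    if len(acts) == 1:
        lead = trail = afcl_ms
    else:
        lead = acts[1] - acts[0]
        trail = acts[-1] - acts[-2]
    # extend with one virtual activation on each side so interior snapshots
    # use the true intervals and edge snapshots the adjacent one
    ext = np.concatenate([[acts[0] - lead], acts, [acts[-1] + trail]])
    idx = np.searchsorted(ext, t, side="right") - 1
    idx = np.clip(idx, 0, len(ext) - 2)
    t_i = ext[idx]
    dt = ext[idx + 1] - ext[idx]
    phi = -_PI + 2 * _PI * (t - t_i) / dt
    return np.clip(phi, -_PI, _PHASE_MAX)


def build_phase(
    acts: ActivationTimes, rate_hz: float, afcl: CycleLengthEstimate
) -> PhaseSnapshotSeries:
    """Linear-interpolation phase embedding sampled at *rate_hz*.

    Between consecutive activations t_i, t_{i+1} the phase is
    phi(t) = -pi + 2*pi*(t - t_i)/(t_{i+1} - t_i), so it equals -pi at the
    activation instant and approaches pi just before the next one.  Before
    the first and after the last activation the ramp is extrapolated with
    the nearest interval (AFCL if the electrode has a single activation)
    and clipped to [-pi, pi).  Electrodes with no activations are flagged
    invalid.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    step = 1000.0 / rate_hz
    t = np.arange(0.0, acts.duration_ms, step)
    n, k = len(t), acts.n_electrodes
    phase = np.zeros((n, k))
    valid = np.ones((n, k), dtype=bool)
    for j, a in enumerate(acts.times):
        if len(a) == 0:
            valid[:, j] = False
            continue
        phase[:, j] = _electrode_phase(t, a, afcl.afcl_ms)
    return PhaseSnapshotSeries(t, phase, valid, float(rate_hz))
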