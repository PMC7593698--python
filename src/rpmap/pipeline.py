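"""End-to-end analysis pipeline and sensitivity sweeps.

``analyze`` runs annotate → phase → distance → threshold → erode →
detect → cluster → characterize on in-memory inputs; ``run_analysis``
wraps it with file I/O and a machine-readable manifest.  ``run_sweep``
re-runs the threshold-dependent stages over parameter grids while
reusing the cached distance matrix (thresholding is cheap, the distance
matrix is the quadratic cost).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterize as char
from .annotate import (
    ActivationTimes,
    CycleLengthEstimate,
    PhaseSnapshotSeries,
    build_phase,
    detect_activations,
    estimate_afcl,
)
from .cluster import (
    PatternCluster,
    cluster_intervals,
    clusters_to_frame,
    filter_clusters,
    interval_similarity,
)
from .detect import (
    DurationProfile,
    RepetitiveInterval,
    detect_intervals,
    duration_profile,
)
from .layout import ElectrodeLayout
from .recurrence import (
    DistanceMatrix,
    RecurrencePlot,
    adaptive_threshold,
    distance_matrix,
    erode,
    recurrence_rate_per_cycle,
    threshold_plot,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze", "run_analysis", "run_sweep"]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    rr_max : target recurrence rate per AF cycle for the adaptive
        threshold (default 1).
    rr_min : minimum block recurrence rate per cycle for a repetitive
        interval, also the cluster-tree cut (default 0.9).
    dt_ms : fixed activation-time-difference threshold for the fixed-mode
        pattern size (default 10 ms).
    rate_hz : phase snapshot (analysis) rate.
    delta_max : optional fixed distance threshold overriding the adaptive one.
    min_cluster_cycles : combined-duration filter for reported clusters.
    """

    rr_max: float = 1.0
    rr_min: float = 0.9
    dt_ms: float = 10.0
    rate_hz: float = 100.0
    delta_max: float | None = None
    min_cluster_cycles: float = 10.0
    linkage: str = "average"
    exclude_band: bool = True
    block_step: int | None = None
    refractory_ms: float = 50.0
    slope_percentile: float = 0.95
    seed: int = 0
    rr_max_grid: list[float] = field(default_factory=list)
    rr_min_grid: list[float] = field(default_factory=list)
    delta_max_grid: list[float] = field(default_factory=list)
    dt_grid: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rr_max <= 0 or self.rr_min <= 0 or self.dt_ms <= 0:
            raise ValueError("rr_max, rr_min and dt_ms must all be > 0")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class AnalysisResult:
    """Bundle of every intermediate and final product of one analysis."""

    config: AnalysisConfig
    layout: ElectrodeLayout
    acts: ActivationTimes
    afcl: CycleLengthEstimate
    phases: PhaseSnapshotSeries
    dm: DistanceMatrix
    delta_max: float
    rp_raw: RecurrencePlot
    rp: RecurrencePlot  # eroded
    profile: DurationProfile
    intervals: list[RepetitiveInterval]
    similarity: np.ndarray
    clusters: list[PatternCluster]  # after the combined-duration filter
    all_clusters: list[PatternCluster]
    summaries: list[char.PatternSummary]
    timings: dict = field(default_factory=dict)

    def interval_table(self) -> pd.DataFrame:
        step = 1000.0 / self.phases.rate_hz
        idx = self.dm.snapshot_index
        rows = []
        for i, iv in enumerate(self.intervals):
            rows.append(
                {
                    "interval_id": i,
                    "start_ms": idx[iv.start] * step,
                    "end_ms": idx[min(iv.end, len(idx) - 1)] * step,
                    "duration_cycles": iv.duration_cycles,
                    "rr_per_cycle": iv.rr_per_cycle,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["interval_id", "start_ms", "end_ms", "duration_cycles", "rr_per_cycle"],
        )

    def manifest(self) -> dict:
        import scipy

        from . import __version__

        return {
            "versions": {
                "rpmap": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
            },
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "n_electrodes": self.layout.n_electrodes,
            "afcl_ms": self.afcl.afcl_ms,
            "afcl_samples": self.afcl.afcl_samples,
            "n_snapshots": self.dm.n,
            "delta_max": self.delta_max,
            "rr_raw_per_cycle": recurrence_rate_per_cycle(self.rp_raw, exclude_band=True),
            "rr_eroded_per_cycle": recurrence_rate_per_cycle(self.rp),
            "n_intervals": len(self.intervals),
            "n_clusters": len(self.clusters),
            "n_clusters_unfiltered": len(self.all_clusters),
            "max_pattern_cycles": max(
                (c.combined_cycles for c in self.clusters), default=0.0
            ),
            "timings_s": self.timings,
        }


def analyze(
    acts: ActivationTimes,
    layout: ElectrodeLayout,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    """Run the full repetitive-pattern pipeline on activation times."""
    if config is None:
        config = AnalysisConfig()
    timings: dict[str, float] = {}

    def _tic(name, t0):
        timings[name] = round(time.perf_counter() - t0, 4)
        logger.info("stage %-12s %.3fs", name, timings[name])
        return time.perf_counter()

    t0 = time.perf_counter()
    afcl = estimate_afcl(acts, rate_hz=config.rate_hz)
    phases = build_phase(acts, config.rate_hz, afcl)
    t0 = _tic("phase", t0)

    dm = distance_matrix(phases)
    t0 = _tic("distance", t0)

    if config.delta_max is not None:
        delta_max = float(config.delta_max)
    else:
        delta_max = adaptive_threshold(
            dm,
            afcl.afcl_samples,
            config.rr_max,
            exclude_band=config.exclude_band,
            seed=config.seed,
        )
    rp_raw = threshold_plot(dm, delta_max, config.rr_max, afcl.afcl_samples)
    rp = erode(rp_raw, dm)
    t0 = _tic("recurrence", t0)

    profile = duration_profile(rp, config.rr_min, step=config.block_step)
    intervals = detect_intervals(profile)
    t0 = _tic("detect", t0)

    if intervals:
        sim = interval_similarity(rp, intervals)
        all_clusters = cluster_intervals(
            sim, intervals, rr_min=config.rr_min, method=config.linkage
        )
        clusters = filter_clusters(all_clusters, config.min_cluster_cycles)
    else:
        sim = np.zeros((0, 0))
        all_clusters, clusters = [], []
    t0 = _tic("cluster", t0)

    summaries = []
    for c in clusters:
        try:
            summaries.append(
                char.summarize(
                    c.rank,
                    phases,
                    rp,
                    list(c.intervals),
                    layout,
                    afcl,
                    delta_max,
                    dt_ms=config.dt_ms,
                    snapshot_index=dm.snapshot_index,
                )
            )
        except ValueError:
            logger.warning("cluster %d: too few recurrences to summarise", c.rank)
    _tic("characterize", t0)

    return AnalysisResult(
        config=config,
        layout=layout,
        acts=acts,
        afcl=afcl,
        phases=phases,
        dm=dm,
        delta_max=delta_max,
        rp_raw=rp_raw,
        rp=rp,
        profile=profile,
        intervals=intervals,
        similarity=sim,
        clusters=clusters,
        all_clusters=all_clusters,
        summaries=summaries,
        timings=timings,
    )


def _load_inputs(
    acts_csv=None, egm_h5=None, layout_csv=None, config: AnalysisConfig | None = None
) -> tuple[ActivationTimes, ElectrodeLayout]:
    from . import io as rio

    if layout_csv is None:
        raise FileNotFoundError("an electrode layout CSV is required")
    layout = ElectrodeLayout.from_csv(layout_csv)
    if acts_csv is not None:
        acts = ActivationTimes.from_csv(acts_csv, n_electrodes=layout.n_electrodes)
    elif egm_h5 is not None:
        egm, fs = rio.load_electrograms(egm_h5)
        cfg = config or AnalysisConfig()
        acts = detect_activations(
            egm, fs, refractory_ms=cfg.refractory_ms,
            slope_percentile=cfg.slope_percentile,
        )
    else:
        raise FileNotFoundError("need either an activation-time CSV or an electrogram file")
    return acts, layout


def run_analysis(
    out_dir,
    acts_csv=None,
    egm_h5=None,
    layout_csv=None,
    config: AnalysisConfig | None = None,
    render: bool = False,
) -> AnalysisResult:
    """File-to-file pipeline: load inputs, analyze, write tables + manifest."""
    from . import io as rio

    config = config or AnalysisConfig()
    acts, layout = _load_inputs(acts_csv, egm_h5, layout_csv, config)
    res = analyze(acts, layout, config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    res.interval_table().assign(config_hash=chash).to_csv(
        out / "intervals.csv", index=False
    )
    clusters_to_frame(res.clusters).assign(config_hash=chash).to_csv(
        out / "clusters.csv", index=False
    )
    if res.similarity.size:
        pd.DataFrame(res.similarity).to_csv(out / "similarity.csv", index=False)
    for s in res.summaries:
        char.summary_to_frame(s, layout).assign(config_hash=chash).to_csv(
            out / f"pattern_{s.cluster_id}.csv", index=False
        )
    rio.save_recurrence(out / "recurrence.h5", res)
    (out / "manifest.json").write_text(json.dumps(res.manifest(), indent=2))
    if render:
        rio.render_recurrence_plot(res, out / "recurrence.png")
        for s in res.summaries:
            rio.render_pattern(s, layout, out / f"pattern_{s.cluster_id}.png")
    return res


def _sweep_metrics(
    rp_raw: RecurrencePlot,
    dm: DistanceMatrix,
    phases: PhaseSnapshotSeries,
    layout: ElectrodeLayout,
    afcl: CycleLengthEstimate,
    config: AnalysisConfig,
    rr_min: float,
) -> dict:
    rp = erode(rp_raw, dm)
    profile = duration_profile(rp, rr_min, step=config.block_step)
    intervals = detect_intervals(profile)
    row = {
        "delta_max": rp.delta_max,
        "rr_raw": recurrence_rate_per_cycle(rp_raw, exclude_band=True),
        "rr_eroded": recurrence_rate_per_cycle(rp),
        "n_intervals": len(intervals),
        "max_interval_cycles": max((iv.duration_cycles for iv in intervals), default=0.0),
        "max_pattern_cycles": 0.0,
        "pattern_size_cm2": 0.0,
    }
    if intervals:
        sim = interval_similarity(rp, intervals)
        clusters = filter_clusters(
            cluster_intervals(sim, intervals, rr_min=rr_min, method=config.linkage),
            config.min_cluster_cycles,
        )
        if clusters:
            row["max_pattern_cycles"] = max(c.combined_cycles for c in clusters)
            try:
                s = char.summarize(
                    clusters[0].rank, phases, rp, list(clusters[0].intervals),
                    layout, afcl, rp.delta_max, dt_ms=config.dt_ms,
                    snapshot_index=dm.snapshot_index,
                )
                row["pattern_size_cm2"] = s.size_adaptive_cm2
            except ValueError:
                pass
    return row


def run_sweep(
    acts: ActivationTimes,
    layout: ElectrodeLayout,
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Sensitivity sweeps over RR_max, fixed delta_max, and RR_min grids.

    The phase embedding and distance matrix are computed once and reused
    across all grid points.  Returns one tidy table per swept parameter.
    """
    config = config or AnalysisConfig()
    afcl = estimate_afcl(acts, rate_hz=config.rate_hz)
    phases = build_phase(acts, config.rate_hz, afcl)
    dm = distance_matrix(phases)
    out: dict[str, pd.DataFrame] = {}

    def _point(delta_max, rr_max, rr_min):
        rp_raw = threshold_plot(dm, delta_max, rr_max, afcl.afcl_samples)
        return _sweep_metrics(rp_raw, dm, phases, layout, afcl, config, rr_min)

    if config.rr_max_grid:
        rows = []
        for rr_max in config.rr_max_grid:
            if rr_max <= 0:
                logger.warning("skipping invalid rr_max grid point %r", rr_max)
                continue
            d = adaptive_threshold(
                dm, afcl.afcl_samples, rr_max,
                exclude_band=config.exclude_band, seed=config.seed,
            )
            rows.append({"rr_max": rr_max, **_point(d, rr_max, config.rr_min)})
        out["rr_max"] = pd.DataFrame(rows)

    if config.delta_max_grid:
        rows = []
        for d in config.delta_max_grid:
            if not (0.0 <= d <= 0.5):
                logger.warning("skipping invalid delta_max grid point %r", d)
                continue
            rows.append({"fixed_delta_max": d, **_point(d, np.nan, config.rr_min)})
        out["delta_max"] = pd.DataFrame(rows)

    if config.rr_min_grid:
        d = (
            config.delta_max
            if config.delta_max is not None
            else adaptive_threshold(
                dm, afcl.afcl_samples, config.rr_max,
                exclude_band=config.exclude_band, seed=config.seed,
            )
        )
        rows = []
        for rr_min in config.rr_min_grid:
            if rr_min <= 0:
                logger.warning("skipping invalid rr_min grid point %r", rr_min)
                continue
            rows.append({"rr_min": rr_min, **_point(d, config.rr_max, rr_min)})
        out["rr_min"] = pd.DataFrame(rows)

    if config.dt_grid:
        res = analyze(acts, layout, config)
        rows = []
        for dt in config.dt_grid:
            if dt <= 0:
                logger.warning("skipping invalid dt grid point %r", dt)
                continue
            sizes = [
                char.pattern_size(s.delta_kp, layout, afcl, "fixed_dt", dt_ms=dt)
                for s in res.summaries
            ]
            rows.append({"dt_ms": dt, "pattern_size_cm2": max(sizes, default=0.0)})
        out["dt"] = pd.DataFrame(rows)

    return out
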