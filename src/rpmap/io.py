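"""File formats and figure rendering.

Electrograms travel in HDF5 containers (dataset ``egm``, attributes
``fs`` and ``units``); layouts and activation times as CSV; analysis
caches (distance matrix, recurrence plot) in HDF5.  Rendering produces
the standard panels: the recurrence plot with detected intervals in red
and within-cluster cross-recurrences in blue, and per-pattern activation
map / distance heat map / direction quiver panels.
"""

from __future__ import annotations

import h5py
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .characterize import PatternSummary
from .layout import ElectrodeLayout

__all__ = [
    "save_electrograms",
    "load_electrograms",
    "save_recurrence",
    "render_recurrence_plot",
    "render_pattern",
]


def save_electrograms(path, egm: np.ndarray, fs: float, units: str = "mV") -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("egm", data=np.asarray(egm, np.float32))
        d.attrs["fs"] = float(fs)
        d.attrs["units"] = units


def load_electrograms(path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as f:
        d = f["egm"]
        return np.asarray(d), float(d.attrs["fs"])


def save_recurrence(path, result) -> None:
    """Cache the distance matrix and eroded recurrence plot of a result."""
    with h5py.File(path, "w") as f:
        f.create_dataset("distance", data=result.dm.values, compression="gzip")
        f.create_dataset(
            "recurrence", data=result.rp.recurrent, compression="gzip"
        )
        f.create_dataset("snapshot_index", data=result.dm.snapshot_index)
        f.attrs["delta_max"] = result.delta_max
        f.attrs["rr_max"] = result.config.rr_max
        f.attrs["afcl_samples"] = result.afcl.afcl_samples
        f.attrs["rate_hz"] = result.phases.rate_hz


def render_recurrence_plot(result, path) -> None:
    """Recurrence plot with interval (red) and cross-recurrence (blue) overlays."""
    rp = result.rp
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(~rp.recurrent, cmap="gray", interpolation="nearest", origin="lower")
    for c in result.clusters:
        ivs = list(c.intervals)
        for a in ivs:
            for b in ivs:
                if a is b:
                    continue
                ax.add_patch(
                    plt.Rectangle(
                        (b.start, a.start), b.duration, a.duration,
                        fill=False, edgecolor="tab:blue", lw=0.8,
                    )
                )
    for iv in result.intervals:
        ax.add_patch(
            plt.Rectangle(
                (iv.start, iv.start), iv.duration, iv.duration,
                fill=False, edgecolor="tab:red", lw=1.2,
            )
        )
    ax.set_xlabel("snapshot")
    ax.set_ylabel("snapshot")
    ax.set_title(f"eroded recurrence plot (δmax={result.delta_max:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_pattern(summary: PatternSummary, layout: ElectrodeLayout, path) -> None:
    """Activation map, δ_k^p heat map, and conduction-direction quiver."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    x, y = layout.x, layout.y
    sc = axes[0].scatter(x, y, c=summary.activation_map_ms, cmap="viridis", s=30)
    fig.colorbar(sc, ax=axes[0], label="activation time (ms)")
    axes[0].set_title(f"pattern {summary.cluster_id}: activation map")
    sc = axes[1].scatter(
        x, y, c=summary.delta_kp, cmap="magma", s=30, vmin=0, vmax=0.5
    )
    fig.colorbar(sc, ax=axes[1], label="δ$_k^p$ (cycle fraction)")
    axes[1].set_title("recurrent phase distance")
    d = summary.direction
    ok = ~np.isnan(d[:, 0])
    axes[2].quiver(x[ok], y[ok], d[ok, 0], d[ok, 1], scale=25)
    axes[2].set_title("conduction direction")
    for ax in axes:
        ax.set_aspect("equal")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
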