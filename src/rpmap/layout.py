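"""Electrode array geometry.

High-density contact mapping uses regular grids of unipolar electrodes.
The reference device emulated here is a 249-electrode circular array with
2.4 mm inter-electrode spacing; square grids are supported for small test
geometries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ElectrodeLayout", "make_layout"]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Planar electrode array.

    Attributes
    ----------
    electrode_id : (n,) int array of unique labels.
    x, y : (n,) float arrays, coordinates in mm.
    spacing : nominal inter-electrode (nearest-neighbour) distance in mm.
    """

    electrode_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        for name in ("electrode_id", "x", "y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("electrode coordinates must be finite")
        if len(np.unique(self.electrode_id)) != len(self.electrode_id):
            raise ValueError("electrode ids must be unique")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_id)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of coordinates in mm."""
        return np.column_stack([self.x, self.y])

    def area_mm2(self) -> float:
        """Total covered area assuming one spacing² unit cell per electrode."""
        return self.n_electrodes * self.spacing**2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"electrode_id": self.electrode_id, "x_mm": self.x, "y_mm": self.y}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spacing: float | None = None) -> "ElectrodeLayout":
        """Read a layout table (electrode_id, x_mm, y_mm).

        If *spacing* is not given it is inferred as the minimum pairwise
        distance between electrodes.
        """
        df = pd.read_csv(path)
        x = df["x_mm"].to_numpy(float)
        y = df["y_mm"].to_numpy(float)
        if spacing is None:
            from scipy.spatial.distance import pdist

            spacing = float(pdist(np.column_stack([x, y])).min())
        return cls(df["electrode_id"].to_numpy(int), x, y, spacing)


def make_layout(n_electrodes: int, spacing: float, shape: str = "circular") -> ElectrodeLayout:
    """Build a regular electrode array.

    Parameters
    ----------
    n_electrodes : number of sites (>= 4). For ``shape="square"`` it must be
        a perfect square (k×k grid).
    spacing : inter-electrode distance in mm.
    shape : ``"circular"`` clips a square lattice to the smallest disc
        holding at least *n_electrodes* sites, then drops the outermost
        sites (sorted by radius, then angle) to hit the exact count;
        ``"square"`` builds a k×k grid.

    Returns
    -------
    ElectrodeLayout with nearest-neighbour distance equal to *spacing*.
    """
    if n_electrodes < 4:
        raise ValueError("n_electrodes must be >= 4")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")

    if shape == "square":
        k = round(np.sqrt(n_electrodes))
        if k * k != n_electrodes:
            raise ValueError(
                f"square layout requires a perfect-square count, got {n_electrodes}"
            )
        ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        x = (jj.ravel() - (k - 1) / 2) * spacing
        y = (ii.ravel() - (k - 1) / 2) * spacing
    elif shape == "circular":
        # lattice generously larger than the target disc
        k = int(np.ceil(2 * np.sqrt(n_electrodes / np.pi))) + 4
        idx = np.arange(k) - (k - 1) / 2
        xx, yy = np.meshgrid(idx * spacing, idx * spacing, indexing="ij")
        x, y = xx.ravel(), yy.ravel()
        r = np.hypot(x, y)
        theta = np.mod(np.arctan2(y, x), 2 * np.pi)
        # deterministic: radius (rounded to break float ties), then angle
        order = np.lexsort((theta, np.round(r, 9)))
        if len(order) < n_electrodes:  # pragma: no cover - lattice oversized
            raise ValueError("internal lattice too small")
        keep = order[:n_electrodes]
        x, y = x[keep], y[keep]
    else:
        raise ValueError(f"unknown shape {shape!r}")

    return ElectrodeLayout(np.arange(len(x)), x, y, float(spacing))
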