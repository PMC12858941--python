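"""Equal-area plane grids and multi-layer predictor stacks.

All spatial data in this package live on an abstract equal-area plane with
coordinates in kilometres.  A :class:`GridSpec` partitions a rectangular
extent into square cells of a fixed edge length; cells are half-open so
every in-extent point belongs to exactly one cell.  An
:class:`EnvironmentStack` holds one 2-D value field per named predictor on
a shared grid, with missingness carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "EnvironmentStack", "assign_cells"]


@dataclass(frozen=True)
class GridSpec:
    """A regular square grid on the planar (km) coordinate system.

    Cell ``(col i, row j)`` covers the half-open square
    ``[origin_x + i*edge, origin_x + (i+1)*edge) x
    [origin_y + j*edge, origin_y + (j+1)*edge)``.
    """

    origin_x: float
    origin_y: float
    cell_edge: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_edge <= 0:
            raise ValueError(f"cell_edge must be > 0, got {self.cell_edge}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(n_rows, n_cols)``."""
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """``(x_min, y_min, x_max, y_max)`` of the covered rectangle."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_edge,
            self.origin_y + self.n_rows * self.cell_edge,
        )

    def coarsen(self, cell_edge: float) -> "GridSpec":
        """A coarser grid with the same origin.

        The new edge must be an integer multiple of the current one.  When
        the extent does not tile exactly, the ragged trailing edge is
        dropped (the coarse grid covers ``floor(n/k)`` blocks per axis).
        """
        ratio = cell_edge / self.cell_edge
        k = int(round(ratio))
        if k < 1 or abs(ratio - k) > 1e-9:
            raise ValueError(
                f"target edge {cell_edge} is not an integer multiple of "
                f"source edge {self.cell_edge}"
            )
        n_cols, n_rows = self.n_cols // k, self.n_rows // k
        if n_cols < 1 or n_rows < 1:
            raise ValueError(f"grid {self.shape} too small for edge {cell_edge}")
        return GridSpec(self.origin_x, self.origin_y, cell_edge, n_cols, n_rows)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as ``(x[n_cols], y[n_rows])`` vectors."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_edge
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_edge
        return xs, ys

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_edge": self.cell_edge,
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            d["origin_x"], d["origin_y"], d["cell_edge"], d["n_cols"], d["n_rows"]
        )


def assign_cells(
    x: np.ndarray, y: np.ndarray, grid: GridSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map points onto grid cells under the half-open floor rule.

    Returns ``(col, row, in_extent)``.  A point exactly on a shared cell
    boundary belongs to the higher-index cell (the boundary is that cell's
    lower edge).  Out-of-extent points get ``in_extent=False`` and
    ``col = row = -1``.

    Parameters
    ----------
    x, y : array-like of point coordinates in km.
    grid : target grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    col = np.floor((x - grid.origin_x) / grid.cell_edge).astype(np.int64)
    row = np.floor((y - grid.origin_y) / grid.cell_edge).astype(np.int64)
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    col = np.where(inside, col, -1)
    row = np.where(inside, row, -1)
    return col, row, inside


@dataclass
class EnvironmentStack:
    """Named 2-D predictor layers sharing one grid.

    Layers are float arrays of shape ``grid.shape``; missing cells are NaN
    (never a sentinel value).  An optional integer ``strata`` layer carries
    a categorical regionalisation (the stand-in for biome categories).
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    strata: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected {self.grid.shape}"
                )
            self.layers[name] = arr
        if self.strata is not None and self.strata.shape != self.grid.shape:
            raise ValueError("strata layer shape mismatch")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def valid_fraction(self) -> np.ndarray:
        """Per-cell fraction of layers with a non-missing value."""
        stack = np.stack([self.layers[n] for n in self.layer_names])
        return np.mean(np.isfinite(stack), axis=0)

    def to_table(self) -> np.ndarray:
        """Flatten to an ``(n_cells, n_layers)`` matrix in row-major cell order."""
        return np.column_stack(
            [self.layers[n].ravel() for n in self.layer_names]
        )
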