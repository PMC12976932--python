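"""Spatial discretization of the screen into a regular grid.

The screen is divided into ``n_rows x n_cols`` rectangular bins (6 x 6 by
default, 36 bins).  Bins are half-open ``[edge, next_edge)`` in both axes,
with the final bin closed so the far screen edges belong to the last
row/column.  Bin indices are row-major: ``index = row * n_cols + col`` where
``row`` indexes y (bottom to top) and ``col`` indexes x (left to right).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    width: float = 1800.0
    height: float = 1000.0
    n_rows: int = 6
    n_cols: int = 6
    x_edges: np.ndarray = field(init=False, repr=False)
    y_edges: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid dimensions must be positive")
        object.__setattr__(
            self, "x_edges", np.linspace(0.0, self.width, self.n_cols + 1)
        )
        object.__setattr__(
            self, "y_edges", np.linspace(0.0, self.height, self.n_rows + 1)
        )

    @property
    def n_bins(self) -> int:
        return self.n_rows * self.n_cols

    def bin_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Row-major bin index per point; -1 for points off screen or NaN.

        The upper edges ``x == width`` / ``y == height`` fall in the last
        column/row (closed upper edge).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        with np.errstate(invalid="ignore"):
            inside = (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)
        xs = np.where(inside, x, 0.0)
        ys = np.where(inside, y, 0.0)
        col = np.floor_divide(xs, self.width / self.n_cols).astype(np.int64, copy=False)
        row = np.floor_divide(ys, self.height / self.n_rows).astype(np.int64, copy=False)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        out = row * self.n_cols + col
        return np.where(inside, out, -1)

    def column_of(self, bin_index: np.ndarray) -> np.ndarray:
        return np.asarray(bin_index) % self.n_cols

    def row_of(self, bin_index: np.ndarray) -> np.ndarray:
        return np.asarray(bin_index) // self.n_cols

    def bin_centers(self) -> np.ndarray:
        """(n_bins, 2) array of (x, y) bin centers in row-major order."""
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(cx, cy)
        return np.column_stack([xx.ravel(), yy.ravel()])
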