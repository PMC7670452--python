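"""Electrode-grid geometry and channel <-> (row, col) mapping.

Coordinate convention used throughout the package: rows are indexed 0-based
top to bottom (proximal to distal), columns 0-based left to right (medial to
lateral). The default channel ordering is column-major (channel 0 is the
upper-left electrode, channel 1 the one below it, ...), switchable to
row-major per grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeGrid", "default_grids", "channels_to_grid", "grid_to_channels"]

#: Standard array geometries: the forearm array has 6 rows and 16-19 columns
#: (depending on forearm circumference); the two upper-arm arrays have 8 rows
#: and 15 columns. Inter-electrode distance is 10 mm in both directions.
STANDARD_GEOMETRIES = {1: (6, 16), 2: (8, 15), 3: (8, 15)}


@dataclass(frozen=True)
class ElectrodeGrid:
    """Geometry and channel map of one 2-D electrode array.

    Parameters
    ----------
    array_id : int
        Array identity: 1 = forearm, 2 = biceps (distal upper arm),
        3 = triceps (proximal upper arm).
    n_rows, n_cols : int
        Grid shape.
    ied_mm : float
        Inter-electrode distance in millimetres (same in x and y).
    order : {"column", "row"}
        Channel ordering convention over the grid.
    origin_offset_cm : tuple of float
        (x, y) distance in cm from the anatomical reference point to the
        upper-left electrode.
    missing : frozenset of int
        Channel indices declared missing (not recorded).
    """

    array_id: int
    n_rows: int
    n_cols: int
    ied_mm: float = 10.0
    order: str = "column"
    origin_offset_cm: tuple[float, float] = (0.0, 0.0)
    missing: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.order not in ("column", "row"):
            raise ValueError(f"unknown channel ordering {self.order!r}")
        if self.array_id == 1:
            if self.n_rows != 6 or not 16 <= self.n_cols <= 19:
                raise ValueError("array 1 must be 6 rows x 16-19 columns")
        elif self.array_id in (2, 3):
            if (self.n_rows, self.n_cols) != (8, 15):
                raise ValueError(f"array {self.array_id} must be 8 rows x 15 columns")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols - len(self.missing)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def channel_position(self, channel: int) -> tuple[int, int]:
        """(row, col) of a channel index under this grid's ordering."""
        if not 0 <= channel < self.n_rows * self.n_cols:
            raise ValueError(f"channel {channel} outside grid with "
                             f"{self.n_rows * self.n_cols} positions")
        if self.order == "column":
            return (channel % self.n_rows, channel // self.n_rows)
        return (channel // self.n_cols, channel % self.n_cols)

    def channel_index(self, row: int, col: int) -> int:
        """Inverse of :meth:`channel_position`."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"position ({row}, {col}) outside {self.shape} grid")
        if self.order == "column":
            return col * self.n_rows + row
        return row * self.n_cols + col

    def neighbor_indices(self, row: int, col: int, radius: int = 1):
        """Channel indices of the (2r+1)^2 - 1 spatial neighbors of (row, col).

        Border electrodes get fewer neighbors; the grid never wraps around.
        """
        out = []
        for r in range(max(0, row - radius), min(self.n_rows, row + radius + 1)):
            for c in range(max(0, col - radius), min(self.n_cols, col + radius + 1)):
                if (r, c) != (row, col):
                    out.append(self.channel_index(r, c))
        return out


def default_grids(forearm_cols: int = 16) -> list[ElectrodeGrid]:
    """The standard three-array montage (forearm, biceps, triceps)."""
    return [
        ElectrodeGrid(array_id=1, n_rows=6, n_cols=forearm_cols),
        ElectrodeGrid(array_id=2, n_rows=8, n_cols=15),
        ElectrodeGrid(array_id=3, n_rows=8, n_cols=15),
    ]


def channels_to_grid(signals: np.ndarray, grid: ElectrodeGrid) -> np.ndarray:
    """Reshape a flat channels x samples matrix onto grid coordinates.

    Returns an array shaped (n_rows, n_cols, n_samples). Declared missing
    channels are filled with NaN rather than silently dropped.
    """
    signals = np.asarray(signals)
    if signals.ndim == 1:
        signals = signals[:, None]
    if signals.shape[0] != grid.n_channels:
        raise ValueError(
            f"got {signals.shape[0]} channels for a grid with {grid.n_channels}")
    out = np.full((grid.n_rows, grid.n_cols, signals.shape[1]), np.nan,
                  dtype=signals.dtype if np.issubdtype(signals.dtype, np.floating)
                  else float)
    k = 0
    for ch in range(grid.n_rows * grid.n_cols):
        if ch in grid.missing:
            continue
        r, c = grid.channel_position(ch)
        out[r, c] = signals[k]
        k += 1
    return out


def grid_to_channels(grid_signals: np.ndarray, grid: ElectrodeGrid) -> np.ndarray:
    """Inverse of :func:`channels_to_grid` (drops declared-missing positions)."""
    grid_signals = np.asarray(grid_signals)
    if grid_signals.shape[:2] != grid.shape:
        raise ValueError(f"expected leading shape {grid.shape}, "
                         f"got {grid_signals.shape[:2]}")
    rows = []
    for ch in range(grid.n_rows * grid.n_cols):
        if ch in grid.missing:
            continue
        r, c = grid.channel_position(ch)
        rows.append(grid_signals[r, c])
    return np.stack(rows)
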