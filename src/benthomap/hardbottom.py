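"""Boulder density gridding and hard-substrate assignment.

Boulder detections (points) are binned into grid cells, cells are graded
into three density classes, and the hard/soft substrate decision is made
per cell from the density class and the mapped sediment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridGeometry",
    "HardSubstrateFlag",
    "grid_boulder_counts",
    "classify_boulder_density",
    "classify_boulder_density_grid",
    "assign_hard_substrate",
    "hard_substrate_mask",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned square grid, row-major from the north-west origin.

    Cell (row, col) covers the half-open square
    ``[x0 + col*w, x0 + (col+1)*w) x (y0 - (row+1)*w, y0 - row*w]``
    where ``(x0, y0)`` is the north-west corner and ``w`` the cell size
    in metres.
    """

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have at least one row and column")

    @property
    def extent_x(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def extent_y(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Return (row, col) of the cell containing a point, or None outside."""
        col = int(np.floor((x - self.x0) / self.cell_size))
        row = int(np.floor((self.y0 - y) / self.cell_size))
        # the northern edge (y == y0) belongs to row 0
        if y == self.y0:
            row = 0
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays of shape (n_rows, n_cols) holding cell centre coordinates."""
        cols = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = self.y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(cols, rows)
        return xx, yy


@dataclass(frozen=True)
class HardSubstrateFlag:
    hard: bool
    provenance: str | None = None  # "boulder_rule" or "reef_polygon"

    def __post_init__(self):
        if self.hard and self.provenance not in ("boulder_rule", "reef_polygon"):
            raise ValueError("hard substrate requires a provenance tag")


def grid_boulder_counts(points: np.ndarray, grid: GridGeometry) -> np.ndarray:
    """Count boulder points per cell.

    ``points`` is an (n, 2) array of x/y coordinates.  Each point is
    counted in exactly one cell (half-open convention); points outside
    the grid extent are excluded with a warning.
    """
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    excluded = 0
    for x, y in points:
        rc = grid.cell_of(x, y)
        if rc is None:
            excluded += 1
        else:
            counts[rc] += 1
    if excluded:
        log.warning("%d boulder point(s) outside the grid extent were excluded", excluded)
    return counts


def classify_boulder_density(count: int) -> int:
    """Grade a per-cell boulder count: 0 -> class 1, 1-5 -> class 2, >5 -> class 3."""
    if count < 0:
        raise ValueError(f"boulder count must be non-negative, got {count}")
    if count == 0:
        return 1
    if count <= 5:
        return 2
    return 3


def classify_boulder_density_grid(counts: np.ndarray) -> np.ndarray:
    if np.any(counts < 0):
        raise ValueError("boulder counts must be non-negative")
    classes = np.ones_like(counts, dtype=int)
    classes[counts >= 1] = 2
    classes[counts > 5] = 3
    return classes


def assign_hard_substrate(boulder_class: int, sediment_class: str) -> HardSubstrateFlag:
    """Hard iff >5 boulders, or 1-5 boulders together with lag sediment."""
    if boulder_class not in (1, 2, 3):
        raise ValueError(f"boulder class must be 1, 2 or 3, got {boulder_class}")
    hard = boulder_class == 3 or (boulder_class == 2 and sediment_class == "LagSed")
    return HardSubstrateFlag(hard=hard, provenance="boulder_rule" if hard else None)


def hard_substrate_mask(
    boulder_classes: np.ndarray | None,
    sediment_classes: np.ndarray | None,
    reef_mask: np.ndarray | None = None,
    detail_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell hard-substrate mask with provenance.

    Inside the detail footprint (``detail_mask``, default everywhere)
    the boulder rule applies; outside it hard substrate comes only from
    reef polygons.  Returns ``(mask, provenance)`` where provenance is
    an object array of {"boulder_rule", "reef_polygon", None}.
    """
    if boulder_classes is not None:
        shape = boulder_classes.shape
    elif reef_mask is not None:
        shape = reef_mask.shape
    else:
        raise ValueError("need boulder classes or a reef mask")
    mask = np.zeros(shape, dtype=bool)
    prov = np.full(shape, None, dtype=object)

    if boulder_classes is not None:
        detail = np.ones(shape, dtype=bool) if detail_mask is None else detail_mask
        lag = (
            sediment_classes == "LagSed"
            if sediment_classes is not None
            else np.zeros(shape, dtype=bool)
        )
        by_rule = detail & ((boulder_classes == 3) | ((boulder_classes == 2) & lag))
        mask |= by_rule
        prov[by_rule] = "boulder_rule"

    if reef_mask is not None:
        new = reef_mask & ~mask
        mask |= reef_mask
        prov[new] = "reef_polygon"
    return mask, prov
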