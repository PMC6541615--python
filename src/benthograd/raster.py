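"""Disturbance raster: 0.5 m grid classified by distance to plough tracks.

Each cell of a grid laid over the mosaic extent records the horizontal
Euclidean distance from its centre to the nearest plough-track stripe (the
centreline buffered by half the track width), and a disturbance level derived
from that distance:

    A: [0, 1) m   B: [1, 10) m   C: [10, 50) m   D: reference (no tracks)

Cells >= 50 m from a track in a tracked scene are UNCLASSIFIED and excluded
from sampling.  Band intervals are half-open so the partition is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely

from .synthetic import ConfigurationError, TrackLayout

__all__ = [
    "LEVEL_CODES",
    "CODE_LEVELS",
    "DEFAULT_BOUNDS",
    "DisturbanceRaster",
    "rasterize",
    "distance_to_tracks",
    "classify",
    "level_areas",
    "track_polygons",
]

LEVEL_CODES = {"UNCLASSIFIED": 0, "A": 1, "B": 2, "C": 3, "D": 4}
CODE_LEVELS = {v: k for k, v in LEVEL_CODES.items()}

#: Band upper bounds in metres for levels A, B, C.
DEFAULT_BOUNDS = (1.0, 10.0, 50.0)


@dataclass(frozen=True)
class DisturbanceRaster:
    """Regular grid over a mosaic extent.

    ``distance`` and ``level`` are ``(n_rows, n_cols)`` arrays (row 0 at the
    southern edge).  ``distance`` is +inf everywhere for a no-track scene;
    ``level`` holds integer codes from :data:`LEVEL_CODES`.
    """

    origin: tuple
    cell_size: float
    n_cols: int
    n_rows: int
    tracked: bool = False
    distance: np.ndarray | None = None
    level: np.ndarray | None = None

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def cell_centres(self):
        """Return (X, Y) coordinate arrays of shape (n_rows, n_cols)."""
        cs = self.cell_size
        x = self.origin[0] + (np.arange(self.n_cols) + 0.5) * cs
        y = self.origin[1] + (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(x, y)

    def cell_index(self, x, y):
        """Flat cell index of point(s); -1 when outside the grid.

        Cells are half-open boxes [lo, hi) in both axes.
        """
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size).astype(int)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(ok, row * self.n_cols + col, -1)


def _n_cells_along(extent: float, cell_size: float) -> int:
    # centre rule: cell i kept iff its centre (i + 0.5) * cs lies strictly
    # inside the extent
    return int(np.ceil(extent / cell_size - 0.5))


def rasterize(scene, cell_size: float = 0.5) -> DisturbanceRaster:
    """Lay a regular grid over the scene extent (grid only, no distances).

    Partial edge cells are kept iff their centre lies inside the extent.
    """
    if cell_size <= 0:
        raise ConfigurationError("cell_size must be > 0")
    if scene.width < cell_size or scene.height < cell_size:
        raise ConfigurationError("extent dimensions must be >= cell_size")
    return DisturbanceRaster(
        origin=tuple(scene.origin),
        cell_size=cell_size,
        n_cols=_n_cells_along(scene.width, cell_size),
        n_rows=_n_cells_along(scene.height, cell_size),
        tracked=not scene.tracks.is_empty,
    )


def track_polygons(tracks: TrackLayout):
    """Shapely (multi)polygon of the track stripes: centrelines buffered by
    width/2 with flat caps.  None for an empty layout."""
    if tracks.is_empty:
        return None
    polys = [
        shapely.buffer(shapely.linestrings(c), tracks.width / 2.0,
                       cap_style="flat")
        for c in tracks.centrelines
    ]
    return shapely.union_all(polys)


def distance_to_tracks(grid: DisturbanceRaster, tracks: TrackLayout) -> DisturbanceRaster:
    """Per-cell-centre Euclidean distance to the nearest track stripe.

    Cell centres inside a stripe get 0.  A no-track layout yields the +inf
    sentinel everywhere.
    """
    if tracks.is_empty:
        dist = np.full((grid.n_rows, grid.n_cols), np.inf)
        return replace(grid, distance=dist, tracked=False)
    poly = track_polygons(tracks)
    X, Y = grid.cell_centres()
    pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
    dist = shapely.distance(pts, poly).reshape(grid.n_rows, grid.n_cols)
    return replace(grid, distance=dist, tracked=True)


def classify(raster: DisturbanceRaster, bounds=DEFAULT_BOUNDS) -> DisturbanceRaster:
    """Assign disturbance levels from the distance field.

    Tracked scene: A [0, b0), B [b0, b1), C [b1, b2), UNCLASSIFIED beyond.
    No-track scene: every cell is level D.
    """
    if raster.distance is None:
        raise ConfigurationError("distance field not computed; run distance_to_tracks")
    b0, b1, b2 = bounds
    if not 0 < b0 < b1 < b2:
        raise ConfigurationError("band bounds must be strictly increasing and > 0")
    d = raster.distance
    level = np.zeros(d.shape, dtype=np.int8)
    if not raster.tracked:
        level[:] = LEVEL_CODES["D"]
    else:
        level[d < b0] = LEVEL_CODES["A"]
        level[(d >= b0) & (d < b1)] = LEVEL_CODES["B"]
        level[(d >= b1) & (d < b2)] = LEVEL_CODES["C"]
    return replace(raster, level=level)


def level_areas(raster: DisturbanceRaster) -> dict:
    """Hectares per level (cell count x cell area), UNCLASSIFIED included."""
    if raster.level is None:
        raise ConfigurationError("raster not classified")
    out = {}
    for name, code in LEVEL_CODES.items():
        n = int(np.sum(raster.level == code))
        out[name] = n * raster.cell_area / 1e4
    return out
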