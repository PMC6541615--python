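"""A-posteriori stratified random composite sampling units.

Within each disturbance level, raster cells are drawn uniformly at random
without replacement and pooled into composite sampling units of a fixed cell
count (default 14,000 cells = 3500 m^2 at 0.5 m resolution).  The units are
deliberately *non-contiguous*: randomisation destroys the spatial coherence
of the data and with it small-scale spatial autocorrelation, so each unit can
be treated as an independent replicate.  Users expecting quadrats should note
that a unit is a scattered set of cells, not a block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import CODE_LEVELS, LEVEL_CODES, DisturbanceRaster

__all__ = [
    "SamplingUnit",
    "AbundanceMatrix",
    "FeasibilityError",
    "DEFAULT_CELLS_PER_UNIT",
    "DEFAULT_REPLICATES",
    "allocate_units",
    "assign_specimens",
]

DEFAULT_CELLS_PER_UNIT = 14_000
DEFAULT_REPLICATES = {"A": 5, "B": 5, "C": 5, "D": 10}


class FeasibilityError(ValueError):
    """A level has fewer cells than the requested design needs."""


@dataclass(frozen=True)
class SamplingUnit:
    unit_id: str
    level: str
    replicate: int
    cell_indices: np.ndarray  # flat raster cell indices, unit-size exactly

    def __post_init__(self):
        object.__setattr__(
            self, "cell_indices", np.asarray(self.cell_indices, dtype=np.int64)
        )


@dataclass
class AbundanceMatrix:
    """Unit x morphospecies counts with per-unit metadata.

    ``counts``: DataFrame indexed by unit id, one column per morphospecies.
    ``meta``: DataFrame (same index) with level, replicate and area_m2.
    ``n_dropped``: specimens outside the raster or in unsampled cells.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    n_dropped: int = 0

    @property
    def levels(self) -> pd.Series:
        return self.meta["level"]


def allocate_units(
    raster: DisturbanceRaster,
    cells_per_unit: int = DEFAULT_CELLS_PER_UNIT,
    replicates: dict = None,
    seed: int = 0,
    prefix: str = "",
) -> list:
    """Randomly allocate same-level cells into disjoint composite units.

    Each requested level draws ``cells_per_unit * replicates[level]`` cells
    uniformly without replacement from that level's classified cells, using an
    independent per-level substream of ``seed`` (so adding a level never
    perturbs another level's draw).  Raises :class:`FeasibilityError` when a
    level cannot supply the cells.
    """
    if replicates is None:
        replicates = dict(DEFAULT_REPLICATES)
    if raster.level is None:
        raise ValueError("raster must be classified before allocation")
    if cells_per_unit <= 0:
        raise ValueError("cells_per_unit must be > 0")
    flat = raster.level.ravel()
    units = []
    for level in sorted(replicates):
        n_rep = int(replicates[level])
        if n_rep == 0:
            continue
        code = LEVEL_CODES[level]
        pool = np.flatnonzero(flat == code)
        need = cells_per_unit * n_rep
        if pool.size < need:
            raise FeasibilityError(
                f"level {level}: {pool.size} cells available but "
                f"{need} required ({n_rep} units of {cells_per_unit} cells)"
            )
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(code,)))
        chosen = rng.choice(pool, size=need, replace=False)
        for r in range(n_rep):
            units.append(
                SamplingUnit(
                    unit_id=f"{prefix}{level}{r + 1}",
                    level=level,
                    replicate=r + 1,
                    cell_indices=np.sort(chosen[r * cells_per_unit:(r + 1) * cells_per_unit]),
                )
            )
    return units


def assign_specimens(table: pd.DataFrame, raster: DisturbanceRaster, units) -> AbundanceMatrix:
    """Tabulate specimens into unit x morphospecies counts.

    Each specimen maps to the half-open cell containing its point; specimens
    outside the raster or in unsampled cells are dropped and counted in
    ``n_dropped``.
    """
    cell_to_unit = np.full(raster.n_cells, -1, dtype=np.int64)
    for j, u in enumerate(units):
        if np.any(cell_to_unit[u.cell_indices] >= 0):
            raise ValueError(f"unit {u.unit_id} overlaps a previously allocated unit")
        cell_to_unit[u.cell_indices] = j
    cell = raster.cell_index(table["x_m"].to_numpy(), table["y_m"].to_numpy()) \
        if len(table) else np.empty(0, dtype=int)
    unit_of = np.where(cell >= 0, cell_to_unit[cell], -1)
    kept = unit_of >= 0
    n_dropped = int(len(table) - kept.sum())

    unit_ids = [u.unit_id for u in units]
    sub = pd.DataFrame(
        {
            "unit": pd.Categorical.from_codes(unit_of[kept], categories=unit_ids),
            "morphospecies": table.loc[kept, "morphospecies"].to_numpy(),
        }
    )
    counts = (
        sub.groupby(["unit", "morphospecies"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(unit_ids, fill_value=0)
    )
    counts.index.name = "unit_id"
    counts.columns.name = "morphospecies"
    area = raster.cell_area
    meta = pd.DataFrame(
        {
            "level": [u.level for u in units],
            "replicate": [u.replicate for u in units],
            "area_m2": [len(u.cell_indices) * area for u in units],
        },
        index=pd.Index(unit_ids, name="unit_id"),
    )
    return AbundanceMatrix(counts=counts, meta=meta, n_dropped=n_dropped)
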