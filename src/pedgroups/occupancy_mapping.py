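"""Tile-based waiting-occupation maps, stratified by group size or waiting
time.

The measurement area is tiled with squares of side Δx (default 0.5 m,
about one shoulder width).  For every frame and every pedestrian of the
chosen stratum that is flagged waiting at that frame, the tile under the
pedestrian is incremented; dividing the per-tile totals by the number of
observation frames N_f gives the waiting occupation

    O_wait(tile) = (waiting pedestrian-frames in tile) / N_f,

i.e. the mean number of waiting pedestrians in the tile per frame,
expressible as a percentage of the observation time.  Because the sum runs
over pedestrians, a tile shared by several waiting pedestrians can exceed
one; such tiles are flagged in the grid's metadata rather than clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .kinematics import WaitingProfile, waiting_bin
from .platform_geometry import PlatformGeometry
from .trajectory_io import TrajectoryDataset

__all__ = [
    "OccupancyGrid",
    "DEFAULT_TILE_SIZE_M",
    "SIZE_STRATA",
    "size_stratum",
    "occupancy_map",
    "stratify",
]

DEFAULT_TILE_SIZE_M = 0.5

#: Group-size strata used for waiting-place comparisons.
SIZE_STRATA = ("individual", "2-3", "4-5", "6+")


def size_stratum(group_size: int | None) -> str:
    """Map a pedestrian's group size (None for no group) to its stratum."""
    if group_size is None or group_size < 2:
        return SIZE_STRATA[0]
    if group_size <= 3:
        return SIZE_STRATA[1]
    if group_size <= 5:
        return SIZE_STRATA[2]
    return SIZE_STRATA[3]


@dataclass
class OccupancyGrid:
    """Per-tile waiting-occupation values on a regular square tiling.

    ``counts[ix, iy]`` is the integer number of waiting pedestrian-frames
    in the tile; ``values`` divides by the frame normaliser ``n_frames``.
    Tiles are half-open, ``[x0 + ix*Δx, x0 + (ix+1)*Δx)``; positions on the
    top/right boundary of the gridded area fall into the last tile.
    Positions outside the grid are excluded and tallied in ``n_overflow``.
    """

    origin: tuple[float, float]
    tile_size: float
    counts: np.ndarray
    n_frames: int
    n_overflow: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array (nx, ny)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def values(self) -> np.ndarray:
        """O_wait per tile (waiting pedestrian-frames / N_f)."""
        return self.counts / float(self.n_frames)

    @property
    def tiles_over_unity(self) -> list[tuple[int, int]]:
        """Tiles whose occupation exceeds 1 (several co-occupying waiters)."""
        ix, iy = np.nonzero(self.counts > self.n_frames)
        return list(zip(ix.tolist(), iy.tolist()))

    @property
    def total_waiting_frames(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, sink: str | Path) -> None:
        """Write the value matrix as CSV (rows = y tiles top-down)."""
        nx, ny = self.shape
        x0, y0 = self.origin
        cols = [x0 + (i + 0.5) * self.tile_size for i in range(nx)]
        rows = [y0 + (j + 0.5) * self.tile_size for j in range(ny)]
        frame = pd.DataFrame(self.values.T[::-1], index=rows[::-1], columns=cols)
        frame.index.name = "y_centre"
        frame.to_csv(sink)


def _grid_frame(area) -> tuple[float, float, float, float]:
    if isinstance(area, PlatformGeometry):
        return area.measurement_area.bounds
    xmin, ymin, xmax, ymax = map(float, area)
    return xmin, ymin, xmax, ymax


def occupancy_map(
    dataset: TrajectoryDataset,
    profiles: Mapping[int | str, WaitingProfile],
    area,
    tile_size: float = DEFAULT_TILE_SIZE_M,
    n_frames: int | None = None,
    include_ids=None,
) -> OccupancyGrid:
    """Accumulate waiting pedestrian-frames into tiles.

    ``area`` is a :class:`PlatformGeometry` (the grid snaps to the bounding
    box of the measurement area) or an explicit ``(xmin, ymin, xmax, ymax)``
    tuple.  ``n_frames`` defaults to the dataset's observation-window span;
    ``include_ids`` restricts the tally to one stratum.
    """
    xmin, ymin, xmax, ymax = _grid_frame(area)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("grid area must have positive extent")
    nx = max(1, math.ceil((xmax - xmin) / tile_size - 1e-9))
    ny = max(1, math.ceil((ymax - ymin) / tile_size - 1e-9))
    counts = np.zeros((nx, ny), dtype=np.int64)
    if n_frames is None:
        n_frames = dataset.n_frames
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    ids = set(profiles) if include_ids is None else set(include_ids) & set(profiles)
    overflow = 0
    for pid in ids:
        profile = profiles[pid]
        frames = profile.waiting_frames
        if frames.size == 0:
            continue
        pos = dataset.trajectories[pid].positions_at(frames)
        ix = np.floor((pos[:, 0] - xmin) / tile_size).astype(np.int64)
        iy = np.floor((pos[:, 1] - ymin) / tile_size).astype(np.int64)
        # top/right boundary of the gridded area belongs to the last tile
        ix[(ix == nx) & np.isclose(pos[:, 0], xmax)] = nx - 1
        iy[(iy == ny) & np.isclose(pos[:, 1], ymax)] = ny - 1
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        overflow += int(np.count_nonzero(~inside))
        np.add.at(counts, (ix[inside], iy[inside]), 1)
    return OccupancyGrid(
        origin=(xmin, ymin),
        tile_size=tile_size,
        counts=counts,
        n_frames=int(n_frames),
        n_overflow=overflow,
    )


def stratify(
    dataset: TrajectoryDataset,
    groups,
    profiles: Mapping[int | str, WaitingProfile],
    classes: Mapping[int | str, str] | None = None,
) -> pd.DataFrame:
    """Per-pedestrian stratum assignments.

    Every pedestrian with a waiting profile receives exactly one group-size
    stratum (``individual`` when in no detected group) and one waiting-time
    bin.  ``classes`` optionally carries boarding/alighting labels into the
    output.
    """
    group_size_of: dict = {}
    for group in groups:
        for pid in group.member_ids:
            group_size_of[pid] = group.size
    rows = []
    for pid, profile in profiles.items():
        size = group_size_of.get(pid)
        rows.append(
            {
                "ped_id": pid,
                "passenger_class": None if classes is None else classes.get(pid),
                "group_size": size,
                "size_stratum": size_stratum(size),
                "total_waiting_s": profile.total_waiting_seconds,
                "waiting_bin": waiting_bin(profile.total_waiting_seconds),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ped_id",
            "passenger_class",
            "group_size",
            "size_stratum",
            "total_waiting_s",
            "waiting_bin",
        ],
    )
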