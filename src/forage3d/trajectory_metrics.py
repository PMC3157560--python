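"""Bin sequences and per-dimension crossing counts.

The movement-anisotropy measure is the number of grid-cell boundaries a
path crosses along each axis: many more horizontal than vertical crossings
means horizontally biased locomotion.  Tracked trajectories are first
binned (5 x 5 regions on the pegboard, 4 x 4 x 4 cubes on the lattice),
consecutive duplicate bins collapsed, and crossings accumulated as the
absolute bin-index change per axis over consecutive samples.

For retrieval routes (observed visit orders or optimised reference routes)
the path between consecutive retrieval bins is taken as the straight
segment between cell centres; because the coordinate along each axis is
monotone over a straight segment, the crossings it contributes per axis
equal the absolute bin-index difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .maze_geometry import MazeSpec


@dataclass(frozen=True)
class Trajectory:
    """Timestamped physical positions (cm) within one maze."""

    t: np.ndarray
    coords: np.ndarray  # (n_samples, n_dims)
    maze: MazeSpec

    def __post_init__(self) -> None:
        if self.t.ndim != 1 or self.coords.shape != (len(self.t), self.maze.n_dims):
            raise ValueError("t must be (n,), coords (n, n_dims)")
        if len(self.t) == 0:
            raise ValueError("empty trajectory")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        ext = np.asarray(self.maze.extent)
        if np.any(self.coords < -1e-9) or np.any(self.coords > ext + 1e-9):
            raise ValueError("coordinates outside maze bounds")


@dataclass(frozen=True)
class CrossingCounts:
    """Accumulated bin/cube crossings per axis."""

    per_axis: tuple[int, ...]
    n_transitions: int

    def __getitem__(self, axis: int) -> int:
        return self.per_axis[axis]


def bin_trajectory(
    traj: Trajectory, median_width: int | None = None
) -> np.ndarray:
    """Map each sample to its containing bin and collapse consecutive
    duplicates.

    Binning is half-open (``floor(coord / cell_size)``): a sample exactly
    on a boundary belongs to the higher-index bin; the top edge of the
    maze is clamped into the last bin.  ``median_width`` optionally applies
    a median filter of that width to the bin indices before collapsing
    (a crude stand-in for tracker smoothing; off by default).
    """
    cell = np.asarray(traj.maze.cell_size)
    shape = np.asarray(traj.maze.grid_shape)
    idx = np.floor(traj.coords / cell).astype(int)
    idx = np.clip(idx, 0, shape - 1)
    if median_width is not None and median_width > 1:
        idx = median_filter(idx, size=(median_width, 1), mode="nearest")
    keep = np.ones(len(idx), dtype=bool)
    keep[1:] = np.any(np.diff(idx, axis=0) != 0, axis=1)
    return idx[keep]


def count_crossings(bins: Sequence[Sequence[int]]) -> CrossingCounts:
    """Per-axis crossings of a bin sequence.

    ``per_axis[a]`` sums ``|Δindex_a|`` over consecutive bin pairs; a
    diagonal bin change increments every changed axis.
    """
    arr = np.asarray(bins, dtype=int)
    if arr.ndim != 2 or len(arr) == 0:
        raise ValueError("need a non-empty (n, n_dims) bin sequence")
    d = np.diff(arr, axis=0)
    per_axis = tuple(int(v) for v in np.abs(d).sum(axis=0))
    n_trans = int(np.any(d != 0, axis=1).sum())
    return CrossingCounts(per_axis=per_axis, n_transitions=n_trans)


def crossings_for_route(route) -> CrossingCounts:
    """Crossing counts of a retrieval route at bin resolution.

    Consecutive retrieval bins are joined by the straight segment between
    their cell centres; along a straight segment each axis coordinate is
    monotone, so the crossings contributed per axis equal ``|Δindex|``.
    """
    bins = np.asarray(
        [route.layout.baited[i] for i in route.order], dtype=int
    )
    return count_crossings(bins)


def crossings_to_frame(
    counts: dict[str, CrossingCounts], maze: MazeSpec
) -> pd.DataFrame:
    rows = []
    for trial_id, cc in counts.items():
        for a, name in enumerate(maze.axis_names):
            rows.append({"trial_id": trial_id, "axis": name, "count": cc.per_axis[a]})
    return pd.DataFrame(rows)


def read_trajectory_csv(path, maze: MazeSpec) -> Trajectory:
    df = pd.read_csv(path)
    cols = [n.lower() for n in maze.axis_names]
    return Trajectory(
        t=df["t"].to_numpy(dtype=float),
        coords=df[cols].to_numpy(dtype=float),
        maze=maze,
    )
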