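"""Discrete geometry of the two climbing apparatuses.

The *pegboard* is a vertical climbing wall carrying a 10 x 10 grid of pegs
at 10 cm spacing, analysed as a 5 x 5 grid of reward regions (each region a
2 x 2 peg array, 20 cm pitch).  It is quasi-two-dimensional: one horizontal
axis (X) and one vertical axis (Z).

The *lattice maze* is a 50 cm climbing cube assembled from tubes, analysed
as 4 x 4 x 4 hollow cubes of 12.5 cm edge.  X and Y are horizontal, Z is
vertical; the origin sits at the front lower-left corner.

All downstream statistics consume the band partitions defined here:

* ``layer``    -- constant-Z band (a horizontal level), both mazes;
* ``column``   -- constant-X band of the pegboard (a vertical strip);
* ``slice_xz`` -- constant-Y slab of the lattice (a vertical X-Z plane);
* ``slice_yz`` -- constant-X slab of the lattice (a vertical Y-Z plane).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Iterator, Sequence

import numpy as np

#: A grid cell, one 0-based integer index per maze axis.
GridPosition = tuple[int, ...]

PEGBOARD = "pegboard"
LATTICE = "lattice"


class GroupingMode(str, Enum):
    """How grid cells are collected into bands for the ordinal-distance
    statistic."""

    LAYER = "layer"
    COLUMN = "column"
    SLICE_XZ = "slice_xz"
    SLICE_YZ = "slice_yz"


@dataclass(frozen=True)
class MazeSpec:
    """Geometry of one apparatus.

    Attributes
    ----------
    name : str
        ``"pegboard"`` or ``"lattice"``.
    grid_shape : tuple of int
        Cells per axis: (5, 5) for the pegboard, (4, 4, 4) for the lattice.
    cell_size : tuple of float
        Cell pitch in cm per axis (pegboard 20 cm regions; lattice 12.5 cm
        cubes).
    axis_names : tuple of str
        Ordered axis labels; exactly one axis is vertical (Z).
    vertical_axis : int
        Index of the vertical axis in ``grid_shape``.
    """

    name: str
    grid_shape: tuple[int, ...]
    cell_size: tuple[float, ...]
    axis_names: tuple[str, ...]
    vertical_axis: int

    @property
    def n_dims(self) -> int:
        return len(self.grid_shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical extent in cm per axis."""
        return tuple(s * c for s, c in zip(self.grid_shape, self.cell_size))

    def positions(self) -> Iterator[GridPosition]:
        """All grid cells in row-major (lowest-axis-fastest-last) order."""
        return product(*(range(s) for s in self.grid_shape))

    def is_valid(self, pos: Sequence[int]) -> bool:
        return len(pos) == self.n_dims and all(
            0 <= p < s for p, s in zip(pos, self.grid_shape)
        )

    def corners(self) -> list[GridPosition]:
        """The 2**n_dims corner cells of the grid."""
        return [tuple(c) for c in product(*((0, s - 1) for s in self.grid_shape))]

    def linear_index(self, pos: Sequence[int]) -> int:
        return int(np.ravel_multi_index(tuple(pos), self.grid_shape))

    # -- serialisation ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "grid_shape": list(self.grid_shape),
                "cell_size": list(self.cell_size),
                "axis_names": list(self.axis_names),
                "vertical_axis": self.vertical_axis,
            }
        )

    @staticmethod
    def from_json(text: str) -> "MazeSpec":
        d = json.loads(text)
        return MazeSpec(
            name=d["name"],
            grid_shape=tuple(d["grid_shape"]),
            cell_size=tuple(d["cell_size"]),
            axis_names=tuple(d["axis_names"]),
            vertical_axis=int(d["vertical_axis"]),
        )


_MODES_BY_MAZE = {
    PEGBOARD: (GroupingMode.LAYER, GroupingMode.COLUMN),
    LATTICE: (GroupingMode.LAYER, GroupingMode.SLICE_XZ, GroupingMode.SLICE_YZ),
}


def make_maze(name: str) -> MazeSpec:
    """Build the spec for one of the two apparatuses.

    >>> make_maze("pegboard").grid_shape
    (5, 5)
    >>> make_maze("lattice").cell_size
    (12.5, 12.5, 12.5)
    """
    if name == PEGBOARD:
        return MazeSpec(
            name=PEGBOARD,
            grid_shape=(5, 5),
            cell_size=(20.0, 20.0),
            axis_names=("X", "Z"),
            vertical_axis=1,
        )
    if name == LATTICE:
        return MazeSpec(
            name=LATTICE,
            grid_shape=(4, 4, 4),
            cell_size=(12.5, 12.5, 12.5),
            axis_names=("X", "Y", "Z"),
            vertical_axis=2,
        )
    raise ValueError(f"unknown maze name {name!r}; expected 'pegboard' or 'lattice'")


@dataclass(frozen=True)
class GroupingAxis:
    """A band partition of one maze's grid (see :class:`GroupingMode`)."""

    mode: GroupingMode
    maze: MazeSpec

    def __post_init__(self) -> None:
        if self.mode not in _MODES_BY_MAZE[self.maze.name]:
            raise ValueError(
                f"grouping mode {self.mode.value!r} is incompatible with the "
                f"{self.maze.name} ({self.maze.n_dims}D) maze"
            )

    @property
    def axis_index(self) -> int:
        """The grid axis whose index identifies the band."""
        if self.mode is GroupingMode.LAYER:
            return self.maze.vertical_axis
        if self.mode is GroupingMode.COLUMN:
            return 0  # pegboard X
        if self.mode is GroupingMode.SLICE_XZ:
            return 1  # lattice Y (constant-Y slabs)
        return 0  # SLICE_YZ: lattice X (constant-X slabs)

    @property
    def n_bands(self) -> int:
        return self.maze.grid_shape[self.axis_index]


def grouping_modes(maze: MazeSpec) -> tuple[GroupingMode, ...]:
    """The band partitions defined for a maze (layer+column on the
    pegboard, layer+two slices on the lattice)."""
    return _MODES_BY_MAZE[maze.name]


def group_of(pos: Sequence[int], axis: GroupingAxis) -> int:
    """Band index (0-based) of a grid cell along a grouping axis."""
    if not axis.maze.is_valid(pos):
        raise ValueError(f"position {tuple(pos)} invalid for {axis.maze.name}")
    return int(pos[axis.axis_index])


def to_physical(pos: Sequence[int], maze: MazeSpec) -> np.ndarray:
    """Cell-centre coordinate in cm: ``(index + 0.5) * cell_size`` per axis."""
    if not maze.is_valid(pos):
        raise ValueError(f"position {tuple(pos)} invalid for {maze.name}")
    return (np.asarray(pos, dtype=float) + 0.5) * np.asarray(maze.cell_size)
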