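"""Synthetic trial generation: baited layouts, agent visit orders,
trajectories and detour choices.

No public dataset accompanies the foraging experiments, so every
downstream stage is exercised on data generated here under the published
baiting protocols:

* pegboard -- all 25 reward regions baited, the food sitting on one of the
  four pegs of the region (a +/-5 cm offset per axis from the region
  centre), re-drawn per trial;
* lattice  -- 24 baited intersection points, 6 drawn from the 25 (5 x 5)
  intersections of each of the 4 levels; intersections are snapped to the
  nearest 4 x 4 cube bin (ties toward the lower index) for all
  band-resolution statistics, while the physical coordinate keeps the
  intersection offset.

Agents visit the baited positions under explicit strategies (layer or
column boustrophedon, uniform random, greedy nearest-neighbour) so the
ordinal-distance machinery can be validated against orders with known
structure.  Detour choices are Bernoulli draws per journey direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .maze_geometry import (
    GridPosition,
    LATTICE,
    MazeSpec,
    PEGBOARD,
    to_physical,
)

# --------------------------------------------------------------------------
# food layouts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FoodLayout:
    """Baited positions of one trial.

    ``baited`` holds grid cells (bin/cube resolution); ``offsets`` holds the
    physical displacement (cm) of the actual food item from each cell
    centre, so ``physical_positions`` returns the exact coordinates used
    for route lengths.
    """

    maze: MazeSpec
    start: GridPosition
    baited: tuple[GridPosition, ...]
    offsets: np.ndarray  # (n_baited, n_dims) cm
    trial_id: str = "trial"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.start not in self.maze.corners():
            raise ValueError(
                f"start {self.start} is not a corner of the {self.maze.name}"
            )
        n = len(self.baited)
        if self.offsets.shape != (n, self.maze.n_dims):
            raise ValueError("offsets shape must be (n_baited, n_dims)")
        # distinct lattice intersections may share a cube after snapping, so
        # cells are not required to be unique -- only valid
        if not all(self.maze.is_valid(p) for p in self.baited):
            raise ValueError("baited positions must be valid grid cells")

    @property
    def n_baited(self) -> int:
        return len(self.baited)

    @property
    def physical_positions(self) -> np.ndarray:
        """(n_baited, n_dims) coordinates in cm of the food items."""
        centres = np.array([to_physical(p, self.maze) for p in self.baited])
        return centres + self.offsets

    @property
    def start_physical(self) -> np.ndarray:
        return to_physical(self.start, self.maze)


def generate_layout(
    maze: MazeSpec,
    start_corner: Sequence[int],
    seed: int,
    trial_id: str = "trial",
) -> FoodLayout:
    """Draw one trial's baited layout under the maze's baiting protocol.

    Deterministic given ``seed``.  ``start_corner`` must be a corner cell.
    """
    start = tuple(int(i) for i in start_corner)
    if start not in maze.corners():
        raise ValueError(f"{start} is not a corner of the {maze.name}")
    rng = np.random.default_rng(seed)

    if maze.name == PEGBOARD:
        baited = [tuple(p) for p in maze.positions()]  # all 25 regions
        # one of the four pegs of the 2x2 region: +/- half the peg spacing
        offsets = rng.choice([-5.0, 5.0], size=(25, 2))
    elif maze.name == LATTICE:
        baited = []
        off = []
        half = maze.cell_size[0] / 2.0  # 6.25 cm
        for iz in range(maze.grid_shape[2]):
            # 6 of the 25 intersection points (5x5 nodes) of this level
            picks = rng.choice(25, size=6, replace=False)
            picks.sort()
            for lin in picks:
                ix, iy = divmod(int(lin), 5)
                sx, sy = max(ix - 1, 0), max(iy - 1, 0)  # nearest cube, ties low
                baited.append((sx, sy, iz))
                off.append(
                    (
                        ix * maze.cell_size[0] - (sx + 0.5) * maze.cell_size[0],
                        iy * maze.cell_size[1] - (sy + 0.5) * maze.cell_size[1],
                        0.0,
                    )
                )
        offsets = np.array(off)
        assert abs(abs(offsets[:, :2]).max() - half) < 1e-9
    else:  # pragma: no cover - make_maze rejects unknown names first
        raise ValueError(f"unknown maze {maze.name!r}")

    return FoodLayout(
        maze=maze,
        start=start,
        baited=tuple(baited),
        offsets=offsets,
        trial_id=trial_id,
        seed=seed,
    )


# --------------------------------------------------------------------------
# visit sequences
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VisitSequence:
    """Ordered retrieval events of one trial.

    ``order[t]`` is the index into ``layout.baited`` of the position
    retrieved at visit ``t``; the ordinal number of that position is
    ``t + 1`` (ordinals run 1..N in visit order).
    """

    layout: FoodLayout
    order: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("order must not repeat positions")
        if any(i < 0 or i >= self.layout.n_baited for i in self.order):
            raise ValueError("order indexes outside the layout")

    @property
    def n_visits(self) -> int:
        return len(self.order)

    @property
    def positions(self) -> list[GridPosition]:
        return [self.layout.baited[i] for i in self.order]

    @property
    def ordinals(self) -> np.ndarray:
        return np.arange(1, len(self.order) + 1)


class StrategyKind(str, Enum):
    LAYER_SNAKE = "layer_snake"
    COLUMN_SNAKE = "column_snake"
    RANDOM_ORDER = "random_order"
    GREEDY_NEAREST = "greedy_nearest"


@dataclass(frozen=True)
class AgentStrategy:
    kind: StrategyKind
    seed: int = 0


def _nearest_to_start(layout: FoodLayout) -> int:
    d = np.linalg.norm(layout.physical_positions - layout.start_physical, axis=1)
    return int(np.argmin(d))  # argmin ties resolve toward the lower index


def _snake_order(layout: FoodLayout, band_axis: int) -> list[int]:
    """Boustrophedon: exhaust each band along ``band_axis`` before moving to
    the next, starting from the band and side nearest the start corner."""
    maze = layout.maze
    shape = maze.grid_shape
    other = [a for a in range(maze.n_dims) if a != band_axis]
    # traverse bands away from the start corner
    asc_band = layout.start[band_axis] == 0
    bands = range(shape[band_axis]) if asc_band else range(shape[band_axis] - 1, -1, -1)
    baited = np.array(layout.baited)
    order: list[int] = []
    for bi, b in enumerate(bands):
        members = np.flatnonzero(baited[:, band_axis] == b)
        if members.size == 0:
            continue
        # sort within the band: secondary axes boustrophedon, alternating
        # direction per band so consecutive bands join at the same side
        keys = []
        for depth, a in enumerate(reversed(other)):
            asc = layout.start[a] == 0
            flip = (bi % 2 == 1) if depth == 0 else False
            vals = baited[members, a]
            keys.append(-vals if asc == flip else vals)
        members = members[np.lexsort(keys[::-1])]
        order.extend(int(m) for m in members)
    return order


def simulate_visits(layout: FoodLayout, strategy: AgentStrategy) -> VisitSequence:
    """Visit every baited position once under the given strategy.

    Random and greedy orders begin at the baited position nearest the
    start corner; snake orders begin at the start-side end of the start
    corner's band.  Deterministic given ``strategy.seed``.
    """
    maze = layout.maze
    n = layout.n_baited
    if strategy.kind is StrategyKind.LAYER_SNAKE:
        order = _snake_order(layout, maze.vertical_axis)
    elif strategy.kind is StrategyKind.COLUMN_SNAKE:
        order = _snake_order(layout, 0)
    elif strategy.kind is StrategyKind.RANDOM_ORDER:
        rng = np.random.default_rng(strategy.seed)
        first = _nearest_to_start(layout)
        rest = [i for i in range(n) if i != first]
        order = [first] + [int(i) for i in rng.permutation(rest)]
    elif strategy.kind is StrategyKind.GREEDY_NEAREST:
        coords = layout.physical_positions
        first = _nearest_to_start(layout)
        order = [first]
        remaining = [i for i in range(n) if i != first]
        while remaining:
            cur = coords[order[-1]]
            d = np.linalg.norm(coords[remaining] - cur, axis=1)
            nxt = remaining.pop(int(np.argmin(d)))  # ties: lower linear index
            order.append(nxt)
    else:  # pragma: no cover
        raise ValueError(f"unknown strategy {strategy.kind!r}")
    return VisitSequence(layout=layout, order=tuple(order))


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------


def visits_to_trajectory(
    seq: VisitSequence, sampling_rate: float, speed: float
):
    """Piecewise-linear timestamped path through the visit order.

    The agent moves at constant ``speed`` (cm/s) along straight segments
    between consecutive food positions; positions are sampled at
    ``sampling_rate`` Hz from t = 0 to the arrival time at the last
    position (which is always included as a final sample).
    """
    from .trajectory_metrics import Trajectory

    if sampling_rate <= 0 or speed <= 0:
        raise ValueError("sampling_rate and speed must be positive")
    coords = seq.layout.physical_positions[list(seq.order)]
    if len(coords) == 1:
        return Trajectory(
            t=np.array([0.0]), coords=coords.copy(), maze=seq.layout.maze
        )
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    arrival = np.concatenate([[0.0], np.cumsum(seg)]) / speed
    total = arrival[-1]
    n_samp = int(np.floor(total * sampling_rate + 1e-9)) + 1
    t = np.arange(n_samp) / sampling_rate
    if t[-1] < total - 1e-9:
        t = np.append(t, total)
    pos = np.column_stack(
        [np.interp(t, arrival, coords[:, a]) for a in range(coords.shape[1])]
    )
    return Trajectory(t=t, coords=pos, maze=seq.layout.maze)


# --------------------------------------------------------------------------
# detour choices
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DetourChoiceModel:
    """Bernoulli route-choice generator for the barrier detour task.

    ``p_horizontal_first`` maps journey direction (``"up"`` / ``"down"``)
    to the probability of choosing the detour whose first leg is
    horizontal.
    """

    p_horizontal_first: dict = field(
        default_factory=lambda: {"up": 0.9, "down": 0.5}
    )
    n_rats: int = 6
    n_trials_per_rat: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for d, p in self.p_horizontal_first.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_horizontal_first[{d!r}]={p} outside [0, 1]")
        if self.n_rats < 1 or self.n_trials_per_rat < 1:
            raise ValueError("n_rats and n_trials_per_rat must be >= 1")


def simulate_detours(
    model: DetourChoiceModel, barrier: str = "symmetric"
) -> pd.DataFrame:
    """One choice record per rat x trial x direction; Bernoulli(p) per
    direction condition.  Deterministic given ``model.seed``."""
    rng = np.random.default_rng(model.seed)
    rows = []
    for rat in range(model.n_rats):
        for trial in range(1, model.n_trials_per_rat + 1):
            for direction, p in model.p_horizontal_first.items():
                choice = (
                    "horizontal_first" if rng.random() < p else "vertical_first"
                )
                rows.append(
                    {
                        "rat": f"r{rat:02d}",
                        "trial": trial,
                        "direction": direction,
                        "barrier": barrier,
                        "choice": choice,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# CSV interchange
# --------------------------------------------------------------------------


def layouts_to_frame(layouts: Sequence[FoodLayout]) -> pd.DataFrame:
    rows = []
    for lay in layouts:
        axes = lay.maze.axis_names
        for i, pos in enumerate(lay.baited):
            row = {
                "maze": lay.maze.name,
                "trial_id": lay.trial_id,
                "seed": lay.seed,
                "bait_index": i,
            }
            for a, name in enumerate(axes):
                row[f"start_{name}"] = lay.start[a]
                row[f"idx_{name}"] = pos[a]
                row[f"off_{name}"] = lay.offsets[i, a]
            rows.append(row)
    return pd.DataFrame(rows)


def layouts_from_frame(df: pd.DataFrame) -> list[FoodLayout]:
    from .maze_geometry import make_maze

    layouts = []
    for trial_id, g in df.groupby("trial_id", sort=False):
        maze = make_maze(g["maze"].iloc[0])
        axes = maze.axis_names
        g = g.sort_values("bait_index")
        start = tuple(int(g[f"start_{a}"].iloc[0]) for a in axes)
        baited = tuple(
            tuple(int(r[f"idx_{a}"]) for a in axes) for _, r in g.iterrows()
        )
        offsets = g[[f"off_{a}" for a in axes]].to_numpy(dtype=float)
        seed = g["seed"].iloc[0]
        layouts.append(
            FoodLayout(
                maze=maze,
                start=start,
                baited=baited,
                offsets=offsets,
                trial_id=str(trial_id),
                seed=None if pd.isna(seed) else int(seed),
            )
        )
    return layouts


def visits_to_frame(seqs: Sequence[VisitSequence]) -> pd.DataFrame:
    rows = []
    for seq in seqs:
        axes = seq.layout.maze.axis_names
        for ordinal, idx in enumerate(seq.order, start=1):
            pos = seq.layout.baited[idx]
            row = {
                "trial_id": seq.layout.trial_id,
                "ordinal": ordinal,
                "bait_index": idx,
            }
            for a, name in enumerate(axes):
                row[f"idx_{name}"] = pos[a]
            rows.append(row)
    return pd.DataFrame(rows)


def visits_from_frame(df: pd.DataFrame, layouts: Sequence[FoodLayout]) -> list[VisitSequence]:
    by_id = {lay.trial_id: lay for lay in layouts}
    seqs = []
    for trial_id, g in df.groupby("trial_id", sort=False):
        order = tuple(int(i) for i in g.sort_values("ordinal")["bait_index"])
        seqs.append(VisitSequence(layout=by_id[str(trial_id)], order=order))
    return seqs


def trajectory_to_frame(traj) -> pd.DataFrame:
    cols = {"t": traj.t}
    for a, name in enumerate(traj.maze.axis_names):
        cols[name.lower()] = traj.coords[:, a]
    return pd.DataFrame(cols)
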