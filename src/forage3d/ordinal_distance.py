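"""The ordinal-distance clustering statistic.

Each retrieved food position gets an ordinal number 1..N by visit order.
For a band k (a layer, column or slice) holding n >= 2 retrieved ordinals
x_1..x_n, the band's ordinal distance is the mean absolute pairwise
difference

    OD_k = sum_{i<j} |x_i - x_j| / (n(n-1)/2),

and the trial's OD for that grouping is the average of OD_k over the p
bands with n >= 2.  Small layer OD means items within a horizontal layer
were collected close together in time (the "layer strategy"); comparing
the same order grouped by vertical bands, or against the OD of a
distance-optimal route on the same layout (the OD *ratio*), separates a
dimensional bias from plain distance optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maze_geometry import GroupingAxis, GroupingMode, MazeSpec, group_of
from .synthetic_data import FoodLayout, VisitSequence, generate_layout


@dataclass(frozen=True)
class ODResult:
    """Per-band ordinal distances for one trial and grouping axis."""

    axis: GroupingAxis
    per_group: tuple[tuple[int, float, int], ...]  # (band, OD_k, n_k), n_k >= 2
    mean_od: float
    p: int  # number of bands with n_k >= 2


@dataclass(frozen=True)
class ODRatio:
    axis: GroupingAxis
    observed_od: float
    optimised_od: float
    ratio: float


def _mean_pairwise_absdiff(x: np.ndarray) -> float:
    # O(n log n): for sorted x, sum_{i<j}(x_j - x_i) = sum_i x_i * (2i - n + 1)
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    total = float(np.sum(x * (2 * np.arange(n) - n + 1)))
    return total / (n * (n - 1) / 2)


def od_per_group(seq: VisitSequence, axis: GroupingAxis) -> ODResult:
    """Ordinal distances of one visit order, grouped along ``axis``.

    Bands with fewer than two retrievals are excluded; raises if no band
    has two (p = 0).
    """
    if axis.maze.name != seq.layout.maze.name:
        raise ValueError("grouping axis belongs to a different maze")
    bands = np.array([group_of(pos, axis) for pos in seq.positions])
    ordinals = seq.ordinals
    per_group = []
    for k in range(axis.n_bands):
        xs = ordinals[bands == k]
        if len(xs) >= 2:
            per_group.append((k, _mean_pairwise_absdiff(xs), len(xs)))
    if not per_group:
        raise ValueError("no band holds two or more retrievals (p = 0)")
    mean_od = float(np.mean([od for _, od, _ in per_group]))
    return ODResult(
        axis=axis, per_group=tuple(per_group), mean_od=mean_od, p=len(per_group)
    )


def od_ratio(observed: ODResult, optimised: ODResult) -> ODRatio:
    """Observed OD divided by the OD of the distance-optimal route on the
    same layout and grouping axis."""
    if (
        observed.axis.mode != optimised.axis.mode
        or observed.axis.maze.name != optimised.axis.maze.name
    ):
        raise ValueError("OD results must share the same grouping axis and maze")
    if optimised.mean_od <= 0:
        raise ValueError("optimised OD must be positive")
    return ODRatio(
        axis=observed.axis,
        observed_od=observed.mean_od,
        optimised_od=optimised.mean_od,
        ratio=observed.mean_od / optimised.mean_od,
    )


def od_expectation_random(
    maze: MazeSpec,
    mode: GroupingMode,
    n_mc: int,
    seed: int,
    layout: FoodLayout | None = None,
) -> float:
    """Monte-Carlo null: mean OD over uniformly random visit orders.

    For a uniformly random order the ordinals within any band are a simple
    random sample of 1..N, so the expected OD is (N+1)/3 for every band
    size -- the same for all grouping axes.  If ``layout`` is omitted, a
    fresh layout is drawn per iteration (pegboard layouts share the fixed
    25-region baiting, so this only matters on the lattice).
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    axis = GroupingAxis(mode=mode, maze=maze)
    vals = []
    for i in range(n_mc):
        lay = layout
        if lay is None:
            corner = maze.corners()[0]
            lay = generate_layout(maze, corner, seed=int(rng.integers(2**31)))
        order = tuple(int(j) for j in rng.permutation(lay.n_baited))
        vals.append(od_per_group(VisitSequence(lay, order), axis).mean_od)
    return float(np.mean(vals))
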