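"""Distance-optimal reference routes via a mutation-only genetic algorithm.

The reference for "how clustered would retrievals look if the agent only
minimised travelled distance, blind to gravity" is the shortest open path
through a trial's food positions, anchored at the food position adjacent
to the start corner on the X axis.  The optimiser is a classic
mutation-only GA over open fixed-start tours:

* population of 100 random routes;
* each generation the population is randomly partitioned into quartets,
  each quartet's shortest route survives and produces three offspring by
  flipping (reversing) a random contiguous segment, swapping its two
  endpoints, and sliding (rotating) the segment by one position;
* the incumbent best over all generations is kept, and the whole process
  is restarted from fresh random populations, the shortest route over all
  restarts winning.

Restarts are evolved batched in one vectorised population (selection is
partitioned within restart blocks, so restarts stay independent), which is
what makes the pooled-control studies fast enough to re-run routinely.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import sem

from .maze_geometry import GroupingAxis, grouping_modes
from .ordinal_distance import od_per_group
from .synthetic_data import FoodLayout, VisitSequence
from .trajectory_metrics import CrossingCounts, crossings_for_route

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults are the full-scale profile (10000 generations x 1000
    restarts); :meth:`desk_scale` (20 restarts x 2000 generations) is the
    profile used for the reproducible control studies and converges to the
    same optima on 24-25 position instances, and :meth:`light` is a
    cheaper profile adequate when only a converged-enough reference OD is
    needed (e.g. per-trial ratios in large seed sweeps).
    """

    population_size: int = 100
    group_size: int = 4
    n_mutants_per_survivor: int = 3
    n_generations: int = 10000
    n_restarts: int = 1000
    seed: int = 0
    distance_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.group_size != 1 + self.n_mutants_per_survivor:
            raise ValueError("group_size must equal 1 + n_mutants_per_survivor")
        if self.population_size % self.group_size != 0:
            raise ValueError("population_size must be divisible by group_size")
        if self.n_mutants_per_survivor != 3:
            raise ValueError(
                "offspring are one flip, one swap and one slide per survivor; "
                "n_mutants_per_survivor must be 3"
            )
        if self.distance_metric != "euclidean":
            raise ValueError("only euclidean distances are supported")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "GAConfig":
        return cls(n_generations=2000, n_restarts=20, seed=seed)

    @classmethod
    def light(cls, seed: int = 0) -> "GAConfig":
        return cls(n_generations=500, n_restarts=4, seed=seed)


@dataclass(frozen=True)
class Route:
    """A fixed-start permutation of a layout's baited positions."""

    layout: FoodLayout
    order: tuple[int, ...]
    length: float

    @property
    def positions(self):
        return [self.layout.baited[i] for i in self.order]

    def as_visits(self) -> VisitSequence:
        return VisitSequence(layout=self.layout, order=self.order)


def route_length(order, layout: FoodLayout) -> float:
    """Total Euclidean length (cm) of the open path through the food
    positions in the given order (no return to start)."""
    order = [int(i) for i in order]
    if sorted(order) != list(range(layout.n_baited)):
        raise ValueError("order must be a permutation of the baited positions")
    coords = layout.physical_positions[order]
    return float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum())


def anchor_index(layout: FoodLayout) -> int:
    """Index of the first retrieval position: the food in the bin adjacent
    to the start corner along X (same indices on the other axes); if that
    bin holds no food, the food item nearest that bin's centre."""
    maze = layout.maze
    step = 1 if layout.start[0] == 0 else -1
    target = (layout.start[0] + step,) + tuple(layout.start[1:])
    centre = (np.asarray(target, dtype=float) + 0.5) * np.asarray(maze.cell_size)
    in_bin = [i for i, p in enumerate(layout.baited) if tuple(p) == target]
    coords = layout.physical_positions
    if in_bin:
        d = np.linalg.norm(coords[in_bin] - centre, axis=1)
        return int(in_bin[int(np.argmin(d))])
    d = np.linalg.norm(coords - centre, axis=1)
    return int(np.argmin(d))


def _evolve_batched(
    D: np.ndarray, n: int, first: int, cfg: GAConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    P, R, G = cfg.population_size, cfg.n_restarts, cfg.group_size
    M = R * P
    S = M // G
    rest = np.array([i for i in range(n) if i != first], dtype=np.int64)
    pop = np.empty((M, n), dtype=np.int64)
    pop[:, 0] = first
    pop[:, 1:] = rest[np.argsort(rng.random((M, n - 1)), axis=1)]

    best_len = np.inf
    best_order: np.ndarray | None = None
    rows_s = np.arange(S)
    k = np.arange(n)[None, :]
    block_offsets = (np.arange(R) * P)[:, None]

    for _ in range(cfg.n_generations):
        lengths = D[pop[:, :-1], pop[:, 1:]].sum(axis=1)
        b = int(np.argmin(lengths))
        if lengths[b] < best_len:
            best_len = float(lengths[b])
            best_order = pop[b].copy()

        # natural selection: random disjoint quartets within each restart
        perm = (np.argsort(rng.random((R, P)), axis=1) + block_offsets).ravel()
        grouped = perm.reshape(S, G)
        winners = grouped[rows_s, lengths[grouped].argmin(axis=1)]
        surv = pop[winners]

        # one random segment [i0, j0] per survivor, drawn from 1..n-1 so the
        # anchored first position never mutates
        ij = rng.integers(1, n, size=(S, 2))
        i0 = ij.min(axis=1)[:, None]
        j0 = ij.max(axis=1)[:, None]
        in_seg = (k >= i0) & (k <= j0)

        flip = np.take_along_axis(surv, np.where(in_seg, i0 + j0 - k, k), axis=1)
        swap = surv.copy()
        swap[rows_s, i0[:, 0]], swap[rows_s, j0[:, 0]] = (
            surv[rows_s, j0[:, 0]],
            surv[rows_s, i0[:, 0]],
        )
        slide = np.take_along_axis(
            surv, np.where(in_seg, np.where(k < j0, k + 1, i0), k), axis=1
        )

        spr = S // R
        pop = np.concatenate(
            [
                surv.reshape(R, spr, n),
                flip.reshape(R, spr, n),
                swap.reshape(R, spr, n),
                slide.reshape(R, spr, n),
            ],
            axis=1,
        ).reshape(M, n)

    lengths = D[pop[:, :-1], pop[:, 1:]].sum(axis=1)
    b = int(np.argmin(lengths))
    if lengths[b] < best_len:
        best_len = float(lengths[b])
        best_order = pop[b].copy()
    assert best_order is not None
    return best_order, best_len


def evolve(layout: FoodLayout, cfg: GAConfig) -> Route:
    """Best route over all restarts; deterministic given ``cfg.seed``."""
    n = layout.n_baited
    if n < 2:
        raise ValueError("need at least two baited positions")
    coords = layout.physical_positions
    D = cdist(coords, coords)
    first = anchor_index(layout)
    rng = np.random.default_rng(cfg.seed)
    order, length = _evolve_batched(D, n, first, cfg, rng)
    return Route(layout=layout, order=tuple(int(i) for i in order), length=length)


def brute_force_route(layout: FoodLayout) -> Route:
    """Exhaustive optimum over all fixed-start orders (reference for small
    instances; factorial cost, refuse above 9 positions)."""
    n = layout.n_baited
    if n > 9:
        raise ValueError("exhaustive search limited to 9 positions")
    coords = layout.physical_positions
    D = cdist(coords, coords)
    first = anchor_index(layout)
    rest = [i for i in range(n) if i != first]
    best_order, best_len = None, np.inf
    for perm in itertools.permutations(rest):
        order = (first,) + perm
        ln = sum(D[order[i], order[i + 1]] for i in range(n - 1))
        if ln < best_len:
            best_len, best_order = ln, order
    return Route(layout=layout, order=best_order, length=float(best_len))


@dataclass(frozen=True)
class OptimisedReference:
    """Pooled distance-optimal reference over a set of trial layouts."""

    routes: tuple[Route, ...]
    od_per_trial: pd.DataFrame  # trial_id, mode, mean_od
    crossings_per_trial: pd.DataFrame  # trial_id, axis, count
    summary: pd.DataFrame  # measure, mean, sem, n


def optimised_reference(layouts, cfg: GAConfig) -> OptimisedReference:
    """Evolve one best route per layout and pool its ordinal distances per
    grouping axis and its crossing counts, as mean +/- SEM.

    Per-layout GA seeds derive from ``cfg.seed`` as ``seed + trial index``.
    """
    layouts = list(layouts)
    if not layouts:
        raise ValueError("need at least one layout")
    maze = layouts[0].maze
    modes = grouping_modes(maze)
    routes = []
    od_rows, cross_rows = [], []
    for i, lay in enumerate(layouts):
        route = evolve(lay, replace(cfg, seed=cfg.seed + i))
        routes.append(route)
        visits = route.as_visits()
        for mode in modes:
            try:
                res = od_per_group(visits, GroupingAxis(mode=mode, maze=maze))
            except ValueError:
                log.warning(
                    "trial %s: no %s band holds two retrievals; skipped",
                    lay.trial_id,
                    mode.value,
                )
                continue
            od_rows.append(
                {"trial_id": lay.trial_id, "mode": mode.value, "mean_od": res.mean_od}
            )
        cc = crossings_for_route(route)
        for a, name in enumerate(maze.axis_names):
            cross_rows.append(
                {"trial_id": lay.trial_id, "axis": name, "count": cc.per_axis[a]}
            )
    od_df = pd.DataFrame(od_rows)
    cross_df = pd.DataFrame(cross_rows)

    sum_rows = []
    for mode in modes:
        vals = od_df.loc[od_df["mode"] == mode.value, "mean_od"].to_numpy()
        if len(vals) == 0:
            continue
        sum_rows.append(
            {
                "measure": f"od_{mode.value}",
                "mean": float(vals.mean()),
                "sem": float(sem(vals)) if len(vals) > 1 else float("nan"),
                "n": len(vals),
            }
        )
    for name in maze.axis_names:
        vals = cross_df.loc[cross_df["axis"] == name, "count"].to_numpy(dtype=float)
        sum_rows.append(
            {
                "measure": f"crossings_{name}",
                "mean": float(vals.mean()),
                "sem": float(sem(vals)) if len(vals) > 1 else float("nan"),
                "n": len(vals),
            }
        )
    return OptimisedReference(
        routes=tuple(routes),
        od_per_trial=od_df,
        crossings_per_trial=cross_df,
        summary=pd.DataFrame(sum_rows),
    )


def routes_to_frame(routes) -> pd.DataFrame:
    """Routes as a tidy frame: one row per retrieval rank."""
    rows = []
    for route in routes:
        maze = route.layout.maze
        for rank, i in enumerate(route.order, start=1):
            pos = route.layout.baited[i]
            row = {
                "trial_id": route.layout.trial_id,
                "rank": rank,
                "bait_index": i,
                "route_length": route.length,
            }
            for a, name in enumerate(maze.axis_names):
                row[f"idx_{name}"] = pos[a]
            rows.append(row)
    return pd.DataFrame(rows)


def routes_from_frame(df: pd.DataFrame, layouts) -> list[Route]:
    """Rebuild routes from :func:`routes_to_frame` output; layouts are
    matched by trial_id."""
    by_id = {lay.trial_id: lay for lay in layouts}
    routes = []
    for trial_id, g in df.groupby("trial_id", sort=False):
        lay = by_id[str(trial_id)]
        order = tuple(int(i) for i in g.sort_values("rank")["bait_index"])
        routes.append(
            Route(layout=lay, order=order, length=route_length(order, lay))
        )
    return routes


def pooled_crossings(routes) -> CrossingCounts:
    """Sum crossing counts over routes (mainly for quick inspection)."""
    per_axis = None
    n_trans = 0
    for r in routes:
        cc = crossings_for_route(r)
        per_axis = (
            cc.per_axis
            if per_axis is None
            else tuple(a + b for a, b in zip(per_axis, cc.per_axis))
        )
        n_trans += cc.n_transitions
    return CrossingCounts(per_axis=per_axis, n_transitions=n_trans)
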