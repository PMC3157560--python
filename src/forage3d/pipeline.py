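"""End-to-end orchestration: generate -> simulate -> optimise -> analyse ->
report, with every random draw derived from one master seed.

Child seeds follow a fixed splitting rule: layout seeds are
``seed + trial_index``, agent seeds ``seed + 100000 + trial_index`` and GA
seeds ``seed + 200000 + trial_index``, so any stage can be re-run in
isolation and full runs are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .detour_analysis import tally
from .maze_geometry import (
    GroupingAxis,
    LATTICE,
    MazeSpec,
    PEGBOARD,
    grouping_modes,
    make_maze,
)
from .ordinal_distance import od_per_group, od_ratio
from .route_optimizer import (
    GAConfig,
    OptimisedReference,
    evolve,
    optimised_reference,
    routes_to_frame,
)
from .stats_report import oneway_anova_bonferroni, paired_compare, summarize
from .synthetic_data import (
    AgentStrategy,
    DetourChoiceModel,
    FoodLayout,
    StrategyKind,
    VisitSequence,
    generate_layout,
    layouts_to_frame,
    simulate_detours,
    simulate_visits,
    visits_to_frame,
)
from .trajectory_metrics import crossings_for_route


def balanced_corners(maze: MazeSpec, n: int) -> list[tuple[int, ...]]:
    """Start-corner assignment cycling the protocol's corners.

    Pegboard rats started from all four corners in equal numbers; lattice
    rats started half from the bottom corner and half from the top.
    """
    if maze.name == PEGBOARD:
        cycle = maze.corners()  # 4 corners
    else:
        top = maze.grid_shape[maze.vertical_axis] - 1
        cycle = [(0, 0, 0), (0, 0, top)]
    return [cycle[i % len(cycle)] for i in range(n)]


def generate_control_layouts(
    maze: MazeSpec, n_trials: int, seed: int
) -> list[FoodLayout]:
    """Seeded trial layouts with balanced start corners."""
    corners = balanced_corners(maze, n_trials)
    return [
        generate_layout(maze, corners[i], seed=seed + i, trial_id=f"t{i:03d}")
        for i in range(n_trials)
    ]


def reproduce_controls(
    maze_name: str, n_trials: int = 80, ga: GAConfig | None = None, seed: int = 0
) -> OptimisedReference:
    """The optimised-control study: pooled ordinal distances and crossing
    counts of distance-optimal routes over freshly generated layouts."""
    maze = make_maze(maze_name)
    layouts = generate_control_layouts(maze, n_trials, seed)
    cfg = ga if ga is not None else GAConfig.desk_scale(seed=seed + 200000)
    return optimised_reference(layouts, cfg)


@dataclass(frozen=True)
class RunConfig:
    maze: str = PEGBOARD
    n_rats: int = 8
    n_trials_per_rat: int = 10
    strategy: StrategyKind = StrategyKind.RANDOM_ORDER
    ga: GAConfig = field(default_factory=GAConfig.desk_scale)
    detours: DetourChoiceModel | None = None
    out_dir: str | Path = "forage3d_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rats < 1 or self.n_trials_per_rat < 1:
            raise ValueError("n_rats and n_trials_per_rat must be >= 1")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _rat_of(trial_id: str) -> str:
    """Experimental-unit label: the 'rXX' prefix of 'rXX_tYY' trial ids,
    else the trial id itself (each trial its own unit)."""
    head, _, _ = trial_id.partition("_")
    return head


def analyse_trials(
    visits: list[VisitSequence], routes
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial OD/ratio and crossing tables for paired observed visit
    orders and optimised routes (matched by position in the lists)."""
    if len(visits) != len(routes):
        raise ValueError("visits and routes must pair up one-to-one")
    od_rows, cross_rows = [], []
    for seq, route in zip(visits, routes):
        maze = seq.layout.maze
        trial_id = seq.layout.trial_id
        rat = _rat_of(trial_id)
        opt_visits = route.as_visits()
        for mode in grouping_modes(maze):
            axis = GroupingAxis(mode=mode, maze=maze)
            obs = od_per_group(seq, axis)
            opt = od_per_group(opt_visits, axis)
            od_rows.append(
                {
                    "rat": rat,
                    "trial_id": trial_id,
                    "mode": mode.value,
                    "observed_od": obs.mean_od,
                    "optimised_od": opt.mean_od,
                    "ratio": od_ratio(obs, opt).ratio,
                }
            )
        for label, obj in (("observed", seq), ("optimised", route)):
            cc = crossings_for_route(obj)
            for a, name in enumerate(maze.axis_names):
                cross_rows.append(
                    {
                        "rat": rat,
                        "trial_id": trial_id,
                        "data_type": label,
                        "axis": name,
                        "count": cc.per_axis[a],
                    }
                )
    return pd.DataFrame(od_rows), pd.DataFrame(cross_rows)


def run_experiment(cfg: RunConfig) -> dict:
    """Run the full synthetic experiment and write the bundle to disk.

    Writes layouts, visit sequences, optimised routes, per-trial OD and
    ratio tables, crossing tables, a stats report, optional detour
    summaries and a manifest (seeds, version, file checksums).  Returns
    the manifest dict.
    """
    maze = make_maze(cfg.maze)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rat_corners = balanced_corners(maze, cfg.n_rats)

    layouts: list[FoodLayout] = []
    visits: list[VisitSequence] = []
    routes = []
    idx = 0
    for rat in range(cfg.n_rats):
        for trial in range(cfg.n_trials_per_rat):
            trial_id = f"r{rat:02d}_t{trial:02d}"
            lay = generate_layout(
                maze, rat_corners[rat], seed=cfg.seed + idx, trial_id=trial_id
            )
            layouts.append(lay)
            visits.append(
                simulate_visits(
                    lay, AgentStrategy(cfg.strategy, seed=cfg.seed + 100000 + idx)
                )
            )
            routes.append(evolve(lay, replace(cfg.ga, seed=cfg.seed + 200000 + idx)))
            idx += 1

    od_df, cross_df = analyse_trials(visits, routes)

    files = {
        "layouts.csv": layouts_to_frame(layouts),
        "visits.csv": visits_to_frame(visits),
        "routes.csv": routes_to_frame(routes),
        "od.csv": od_df,
        "crossings.csv": cross_df,
    }

    if cfg.detours is not None:
        det = simulate_detours(cfg.detours)
        files["detours.csv"] = det
        files["detour_summary.csv"] = tally(det, by=("direction",))

    title = (
        f"# forage3d run report ({maze.name}, strategy={cfg.strategy.value})\n\n"
        f"{cfg.n_rats} rats x {cfg.n_trials_per_rat} trials, master seed {cfg.seed}."
    )
    report, summary = build_report(maze, od_df, cross_df, title)
    files["summary.csv"] = summary

    written = {}
    for name, df in files.items():
        _write_csv(df, out / name)
        written[name] = _sha256(out / name)
    (out / "report.md").write_text(report)
    written["report.md"] = _sha256(out / "report.md")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "maze": cfg.maze,
        "strategy": cfg.strategy.value,
        "n_rats": cfg.n_rats,
        "n_trials_per_rat": cfg.n_trials_per_rat,
        "ga": asdict(cfg.ga),
        "files": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def build_report(
    maze: MazeSpec,
    od_df: pd.DataFrame,
    cross_df: pd.DataFrame,
    title: str = "# forage3d analysis report",
) -> tuple[str, pd.DataFrame]:
    """Markdown report plus pooled summary table from per-trial OD and
    crossing tables (per-rat means as the experimental unit)."""
    modes = [m.value for m in grouping_modes(maze)]
    per_rat = {
        m: od_df[od_df["mode"] == m].groupby("rat")["ratio"].mean() for m in modes
    }
    measures = {f"ratio_{m}": per_rat[m].to_numpy() for m in modes}
    for m in modes:
        measures[f"observed_od_{m}"] = (
            od_df[od_df["mode"] == m].groupby("rat")["observed_od"].mean().to_numpy()
        )
        measures[f"optimised_od_{m}"] = (
            od_df[od_df["mode"] == m].groupby("rat")["optimised_od"].mean().to_numpy()
        )
    summary = summarize(measures)

    n_units = od_df["rat"].nunique()
    lines = [
        title,
        "",
        "## Pooled summary (per-rat means)",
        "",
        "```",
        summary.to_string(index=False),
        "```",
        "",
    ]
    if maze.name == PEGBOARD and n_units >= 2:
        a, b = per_rat["layer"].to_numpy(), per_rat["column"].to_numpy()
        try:
            t, dof, p = paired_compare(a, b)
            lines += [
                "## Layer vs column OD ratios (paired t on per-rat means)",
                "",
                f"t({dof}) = {t:.3f}, p = {p:.4g}; "
                f"layer ratio mean {a.mean():.3f}, column ratio mean {b.mean():.3f}.",
                "",
            ]
            if a.mean() < 1.0 < b.mean():
                lines.append(
                    "Layer ratio < 1 < column ratio: horizontally biased "
                    "(layer-strategy) foraging.\n"
                )
        except ValueError:
            pass
    if maze.name == LATTICE and n_units >= 2:
        groups = {m: per_rat[m].to_numpy() for m in modes}
        if all(len(v) >= 2 for v in groups.values()):
            F, (d1, d2), p, pairs = oneway_anova_bonferroni(groups)
            lines += [
                "## OD ratios across groupings (one-way ANOVA, Bonferroni)",
                "",
                f"F({d1},{d2}) = {F:.3f}, p = {p:.4g}",
                "",
                "```",
                pairs.to_string(index=False),
                "```",
                "",
            ]
    return "\n".join(lines), summary
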