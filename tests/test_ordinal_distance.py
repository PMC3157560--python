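import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from forage3d.maze_geometry import GroupingAxis, GroupingMode, MazeSpec
from forage3d.ordinal_distance import (
    _mean_pairwise_absdiff,
    od_expectation_random,
    od_per_group,
    od_ratio,
)
from forage3d.synthetic_data import (
    AgentStrategy,
    FoodLayout,
    StrategyKind,
    VisitSequence,
    generate_layout,
    simulate_visits,
)


def brute_mean_absdiff(xs):
    pairs = list(itertools.combinations(xs, 2))
    return sum(abs(a - b) for a, b in pairs) / len(pairs)


class TestPerBandOD:
    @pytest.mark.parametrize(
        "ordinals,expected",
        [((1, 2), 1.0), ((1, 3, 7), 4.0), ((1, 2, 3, 4, 5), 2.0)],
    )
    def test_hand_examples(self, ordinals, expected):
        assert _mean_pairwise_absdiff(np.array(ordinals)) == pytest.approx(expected)

    @given(st.lists(st.integers(1, 25), min_size=2, max_size=12, unique=True))
    def test_matches_pair_enumeration(self, xs):
        assert _mean_pairwise_absdiff(np.array(xs)) == pytest.approx(
            brute_mean_absdiff(xs)
        )

    def test_distinct_ordinals_give_od_at_least_one(self):
        # minimal separation of distinct integers
        assert _mean_pairwise_absdiff(np.arange(1, 8)) >= 1.0


class TestOdPerGroup:
    def test_boustrophedon_layer_and_column(self, pegboard):
        """The row-snake yields layer OD exactly 2 and column OD exactly 10
        (per-band ordinals {c+1, 10-c, 11+c, 20-c, 21+c})."""
        lay = generate_layout(pegboard, (0, 0), seed=0)
        seq = simulate_visits(lay, AgentStrategy(StrategyKind.LAYER_SNAKE))
        layer = od_per_group(seq, GroupingAxis(GroupingMode.LAYER, pegboard))
        column = od_per_group(seq, GroupingAxis(GroupingMode.COLUMN, pegboard))
        assert layer.mean_od == pytest.approx(2.0)
        assert column.mean_od == pytest.approx(10.0)
        assert layer.p == column.p == 5

    def test_reversal_invariance(self, lattice):
        lay = generate_layout(lattice, (0, 0, 0), seed=1)
        seq = simulate_visits(lay, AgentStrategy(StrategyKind.RANDOM_ORDER, seed=1))
        rev = VisitSequence(lay, tuple(reversed(seq.order)))
        for mode in (GroupingMode.LAYER, GroupingMode.SLICE_XZ, GroupingMode.SLICE_YZ):
            axis = GroupingAxis(mode, lattice)
            assert od_per_group(seq, axis).mean_od == pytest.approx(
                od_per_group(rev, axis).mean_od
            )

    def test_bands_below_two_excluded(self, pegboard):
        lay = FoodLayout(
            maze=pegboard,
            start=(0, 0),
            baited=((0, 0), (0, 1), (1, 3)),
            offsets=np.zeros((3, 2)),
        )
        res = od_per_group(
            VisitSequence(lay, (0, 1, 2)), GroupingAxis(GroupingMode.COLUMN, pegboard)
        )
        assert res.p == 1  # only column 0 holds two retrievals
        assert res.per_group[0][0] == 0

    def test_p_zero_rejected(self, pegboard):
        lay = FoodLayout(
            maze=pegboard,
            start=(0, 0),
            baited=((0, 0), (1, 1)),
            offsets=np.zeros((2, 2)),
        )
        with pytest.raises(ValueError, match="p = 0"):
            od_per_group(
                VisitSequence(lay, (0, 1)), GroupingAxis(GroupingMode.LAYER, pegboard)
            )


class TestOdRatio:
    def test_reported_scale_examples(self, pegboard):
        axis = GroupingAxis(GroupingMode.LAYER, pegboard)
        from forage3d.ordinal_distance import ODResult

        obs = ODResult(axis, ((0, 3.8, 5),), 3.8, 1)
        opt = ODResult(axis, ((0, 5.12, 5),), 5.12, 1)
        assert od_ratio(obs, opt).ratio == pytest.approx(0.742, abs=1e-3)
        obs2 = ODResult(axis, ((0, 7.73, 5),), 7.73, 1)
        opt2 = ODResult(axis, ((0, 5.14, 5),), 5.14, 1)
        assert od_ratio(obs2, opt2).ratio == pytest.approx(1.504, abs=1e-3)

    def test_identical_sequences_give_unity(self, pegboard):
        lay = generate_layout(pegboard, (0, 0), seed=2)
        seq = simulate_visits(lay, AgentStrategy(StrategyKind.RANDOM_ORDER, seed=2))
        res = od_per_group(seq, GroupingAxis(GroupingMode.LAYER, pegboard))
        assert od_ratio(res, res).ratio == pytest.approx(1.0)

    def test_axis_mismatch_rejected(self, pegboard):
        lay = generate_layout(pegboard, (0, 0), seed=2)
        seq = simulate_visits(lay, AgentStrategy(StrategyKind.RANDOM_ORDER, seed=2))
        layer = od_per_group(seq, GroupingAxis(GroupingMode.LAYER, pegboard))
        col = od_per_group(seq, GroupingAxis(GroupingMode.COLUMN, pegboard))
        with pytest.raises(ValueError, match="same grouping axis"):
            od_ratio(layer, col)


class TestRandomNull:
    def test_pegboard_null_matches_closed_form(self, pegboard):
        """E|x - y| over distinct uniform ordinals 1..N is (N+1)/3, so the
        Monte-Carlo null must sit within 3 SE of 26/3."""
        n_mc = 300
        lay = generate_layout(pegboard, (0, 0), seed=0)
        axis = GroupingAxis(GroupingMode.LAYER, pegboard)
        rng = np.random.default_rng(0)
        vals = [
            od_per_group(
                VisitSequence(lay, tuple(int(i) for i in rng.permutation(25))), axis
            ).mean_od
            for _ in range(n_mc)
        ]
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(n_mc)
        assert abs(mean - 26 / 3) < 3 * se
        # and the packaged Monte-Carlo helper agrees
        mc = od_expectation_random(pegboard, GroupingMode.LAYER, 200, seed=1)
        assert abs(mc - 26 / 3) < 0.3

    def test_layer_and_column_nulls_agree(self, pegboard):
        a = od_expectation_random(pegboard, GroupingMode.LAYER, 300, seed=0)
        b = od_expectation_random(pegboard, GroupingMode.COLUMN, 300, seed=1)
        assert a == pytest.approx(b, abs=0.3)

    def test_degenerate_two_positions(self, pegboard):
        lay = FoodLayout(
            maze=pegboard,
            start=(0, 0),
            baited=((0, 0), (0, 1)),
            offsets=np.zeros((2, 2)),
        )
        val = od_expectation_random(
            pegboard, GroupingMode.COLUMN, 10, seed=0, layout=lay
        )
        assert val == pytest.approx(1.0)


def test_toy_grid_no_order_clusters_both_axes_below_snake_sum():
    """Exhaustive 3x3 check: no visit order attains layer OD + column OD
    below the boustrophedon's 4/3 + 4, so horizontal and vertical
    clustering genuinely trade off."""
    maze = MazeSpec(
        name="pegboard",
        grid_shape=(3, 3),
        cell_size=(20.0, 20.0),
        axis_names=("X", "Z"),
        vertical_axis=1,
    )
    baited = tuple((x, z) for z in range(3) for x in range(3))
    lay = FoodLayout(maze=maze, start=(0, 0), baited=baited, offsets=np.zeros((9, 2)))
    layer_axis = GroupingAxis(GroupingMode.LAYER, maze)
    col_axis = GroupingAxis(GroupingMode.COLUMN, maze)

    cols = np.array([p[0] for p in baited])
    rows = np.array([p[1] for p in baited])

    perms = np.array(list(itertools.permutations(range(9))), dtype=np.int8)
    ords = np.empty_like(perms)
    np.put_along_axis(ords, perms.astype(np.intp), np.arange(1, 10, dtype=np.int8), 1)

    def od_all(band_ids):
        # vectorised mean pairwise |diff| of each band's three ordinals
        total = np.zeros(len(perms))
        for b in range(3):
            o = ords[:, band_ids == b].astype(np.int16)
            d = (
                np.abs(o[:, 0] - o[:, 1])
                + np.abs(o[:, 0] - o[:, 2])
                + np.abs(o[:, 1] - o[:, 2])
            )
            total += d / 3.0
        return total / 3.0

    sums = od_all(rows) + od_all(cols)
    best = float(sums.min())
    best_perm = tuple(int(i) for i in perms[int(sums.argmin())])
    assert best == pytest.approx(4 / 3 + 4)
    # the package's od_per_group agrees with the enumeration oracle
    seq = VisitSequence(lay, best_perm)
    total = (
        od_per_group(seq, layer_axis).mean_od + od_per_group(seq, col_axis).mean_od
    )
    assert total == pytest.approx(best)
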