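import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from driftwood.spatial_stats import (
    HexCell,
    aggregate_to_grid,
    assign_catchments,
    distance_decay,
    global_morans_i,
    local_morans_i,
    make_hex_grid,
    mann_whitney_u,
    spearman_rho,
)
from driftwood.synthetic_scene import Catchment


def rook_2x2():
    """2x2 rook-adjacency neighbour lists (binary weights)."""
    neighbors = [[1, 2], [0, 3], [0, 3], [1, 2]]
    weights = [np.ones(2) for _ in range(4)]
    return neighbors, weights


class TestHexGrid:
    def test_tiny_extent_covered(self):
        cells = make_hex_grid((0, 0, 100, 100), cell_size_m=10_000)
        union = unary_union([c.polygon for c in cells])
        assert box(0, 0, 100, 100).difference(union).area < 1e-6

    def test_interior_cell_has_six_neighbors(self):
        cells = make_hex_grid((0, 0, 60_000, 60_000), 10_000)
        counts = [len(c.neighbors) for c in cells]
        assert max(counts) == 6
        assert sum(1 for c in counts if c == 6) > 0

    def test_tessellation_covers_without_overlap(self):
        cells = make_hex_grid((0, 0, 40_000, 30_000), 10_000)
        union = unary_union([c.polygon for c in cells])
        # coverage up to floating-point slivers; no overlap at all
        assert box(0, 0, 40_000, 30_000).difference(union).area < 1e-6
        total = sum(c.polygon.area for c in cells)
        assert total == pytest.approx(union.area, rel=1e-9)

    def test_incircle_diameter_is_cell_size(self):
        cells = make_hex_grid((0, 0, 30_000, 30_000), 10_000)
        c = cells[0].polygon
        # flat-to-flat width of a pointy-top hexagon = incircle diameter
        xs = np.array(c.exterior.coords)[:, 0]
        assert xs.max() - xs.min() == pytest.approx(10_000, rel=1e-9)


class TestAggregate:
    def test_no_deposits_all_zero(self):
        cells = make_hex_grid((0, 0, 30_000, 30_000), 10_000)
        aggregate_to_grid([], cells)
        assert all(c.driftwood_area_m2 == 0 and c.deposit_count == 0 for c in cells)

    def test_deposit_inside_one_cell(self):
        cells = make_hex_grid((0, 0, 30_000, 30_000), 10_000)
        target = cells[len(cells) // 2]
        cx, cy = target.polygon.centroid.x, target.polygon.centroid.y
        dep = box(cx - 15, cy - 15, cx + 15, cy + 15)
        aggregate_to_grid([dep], cells)
        assert target.driftwood_area_m2 == pytest.approx(900.0)
        assert target.deposit_count == 1
        assert sum(c.deposit_count for c in cells) == 1

    def test_straddling_deposit_splits_area_but_not_count(self):
        cells = [
            HexCell(id=0, polygon=box(0, 0, 100, 100), q=0, r=0),
            HexCell(id=1, polygon=box(100, 0, 200, 100), q=1, r=0),
        ]
        dep = box(40, 40, 140, 50)  # 60% in cell 0, 40% in cell 1
        aggregate_to_grid([dep], cells)
        assert cells[0].driftwood_area_m2 == pytest.approx(600.0)
        assert cells[1].driftwood_area_m2 == pytest.approx(400.0)
        assert (cells[0].deposit_count, cells[1].deposit_count) == (1, 0)

    def test_total_area_conserved(self):
        rng = np.random.default_rng(0)
        cells = make_hex_grid((0, 0, 50_000, 50_000), 10_000)
        deps = [Point(rng.uniform(5_000, 45_000), rng.uniform(5_000, 45_000)).buffer(rng.uniform(10, 200))
                for _ in range(40)]
        aggregate_to_grid(deps, cells)
        assert sum(c.driftwood_area_m2 for c in cells) == pytest.approx(sum(d.area for d in deps), rel=1e-6)


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        neighbors, weights = rook_2x2()
        res = global_morans_i([1, 0, 0, 1], neighbors, weights, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(-1.0)

    def test_null_mean_matches_expectation(self):
        rng = np.random.default_rng(1)
        cells = make_hex_grid((0, 0, 80_000, 80_000), 10_000)
        values = rng.random(len(cells))
        res = global_morans_i(values, [c.neighbors for c in cells], n_permutations=999, seed=2)
        n = len(cells)
        se = res.extras["null_sd"] / np.sqrt(res.extras["n_permutations"])
        assert abs(res.extras["null_mean"] - (-1 / (n - 1))) < 3 * se

    def test_constant_field_rejected(self):
        neighbors, weights = rook_2x2()
        with pytest.raises(ValueError, match="constant"):
            global_morans_i([2, 2, 2, 2], neighbors, weights)

    def test_clustered_field_positive_and_significant(self):
        cells = make_hex_grid((0, 0, 100_000, 50_000), 10_000)
        values = np.array([1.0 if c.polygon.centroid.x < 50_000 else 0.0 for c in cells])
        res = global_morans_i(values, [c.neighbors for c in cells], n_permutations=999, seed=3)
        assert res.statistic > 0.3
        assert res.p_value < 0.01


class TestLocalMoran:
    def test_checkerboard_all_negative_no_high_high(self):
        neighbors, weights = rook_2x2()
        li, pp, quad, clusters = local_morans_i([1, 0, 0, 1], neighbors, weights,
                                                n_permutations=99, seed=0)
        assert (li < 0).all()
        assert "high-high" not in quad
        assert clusters == []

    def test_hotspot_labelled_high_high(self):
        cells = make_hex_grid((0, 0, 100_000, 60_000), 10_000)
        values = np.zeros(len(cells))
        # a compact blob of high cells
        centre = min(cells, key=lambda c: c.polygon.centroid.distance(Point(50_000, 30_000)))
        hot = [centre.id] + centre.neighbors
        values[hot] = 10.0
        li, pp, quad, clusters = local_morans_i(values, [c.neighbors for c in cells],
                                                n_permutations=999, alpha=0.05, seed=1)
        assert quad[centre.id] == "high-high"
        assert any(centre.id in cl for cl in clusters)

    def test_alpha_one_puts_every_high_high_in_a_cluster(self):
        cells = make_hex_grid((0, 0, 80_000, 40_000), 10_000)
        rng = np.random.default_rng(2)
        values = rng.random(len(cells))
        li, pp, quad, clusters = local_morans_i(values, [c.neighbors for c in cells],
                                                n_permutations=99, alpha=1.0, seed=3)
        hh = {i for i, q in enumerate(quad) if q == "high-high"}
        in_cluster = set().union(*clusters) if clusters else set()
        assert hh == in_cluster

    def test_local_sums_relate_to_global(self):
        # for row-standardized weights, sum(I_i) / n approximates global I
        cells = make_hex_grid((0, 0, 80_000, 80_000), 10_000)
        rng = np.random.default_rng(4)
        values = rng.random(len(cells)) + np.array(
            [c.polygon.centroid.x / 80_000 for c in cells])
        neighbors = [c.neighbors for c in cells]
        li, _, _, _ = local_morans_i(values, neighbors, n_permutations=19, seed=5)
        g = global_morans_i(values, neighbors, n_permutations=19, seed=5)
        # equality holds up to the S0 normalization: S0 = n for row-standard
        assert li.sum() / len(cells) == pytest.approx(g.statistic, rel=1e-6)


class TestMannWhitney:
    def test_disjoint_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_u_is_half_nm(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)

    def test_single_pair(self):
        res = mann_whitney_u([1], [2], mode="exact")
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1.0)

    @given(
        st.lists(st.integers(0, 10), min_size=2, max_size=7),
        st.lists(st.integers(0, 10), min_size=2, max_size=7),
    )
    @settings(max_examples=40, deadline=None)
    def test_exact_p_matches_scipy_enumeration(self, a, b):
        ours = mann_whitney_u(a, b, mode="exact")
        ties = len(set(a + b)) < len(a + b)
        theirs = sp_stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact" if not ties else "auto")
        assert ours.statistic == pytest.approx(
            sp_stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
        if not ties:
            assert ours.p_value == pytest.approx(theirs.pvalue, abs=1e-9)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 7).tolist()
        b = rng.normal(1, 1, 7).tolist()
        pe = mann_whitney_u(a, b, mode="exact").p_value
        pn = mann_whitney_u(a, b, mode="normal").p_value
        assert pn == pytest.approx(pe, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])


class TestSpearman:
    def test_monotone_is_one(self):
        res = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_hand_computed_triple(self):
        res = spearman_rho([1, 2, 3], [1, 3, 2])
        assert res.statistic == pytest.approx(0.5)

    def test_reversed_is_minus_one(self):
        res = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(4, 12))
    @settings(max_examples=30, deadline=None)
    def test_matches_scipy(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.random(n)
        y = rng.random(n)
        ours = spearman_rho(x, y)
        theirs = sp_stats.spearmanr(x, y)
        assert ours.statistic == pytest.approx(theirs.statistic, abs=1e-12)
        if n > 8:  # both use the t approximation there
            assert ours.p_value == pytest.approx(theirs.pvalue, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


def _three_catchments():
    coast = LineString([(0, 100), (300, 100)])
    catchments = [
        Catchment(id=0, polygon=box(0, 100, 100, 300), forest_fraction=0.8, outlet=Point(50, 100)),
        Catchment(id=1, polygon=box(100, 100, 200, 300), forest_fraction=0.0, outlet=Point(150, 100)),
        Catchment(id=2, polygon=box(200, 100, 300, 300), forest_fraction=0.5, outlet=Point(250, 100)),
    ]
    return coast, catchments


class TestAssignCatchments:
    def test_forested_keeps_assignment(self):
        coast, catchments = _three_catchments()
        ids = assign_catchments([Point(50, 150)], catchments, coast)
        assert ids.tolist() == [0]

    def test_all_forested_identity(self):
        coast, catchments = _three_catchments()
        for c in catchments:
            c.forest_fraction = 0.5
        ids = assign_catchments([Point(50, 150), Point(150, 150), Point(250, 150)], catchments, coast)
        assert ids.tolist() == [0, 1, 2]

    def test_nonforested_reassigned_to_nearest_along_coast(self):
        coast, catchments = _three_catchments()
        # catchment 1 outlet at 150: distance 100 to both; nudge west outlet
        catchments[0].outlet = Point(60, 100)
        ids = assign_catchments([Point(150, 150)], catchments, coast)
        assert ids.tolist() == [0]  # 90 along coast to west vs 100 to east

    def test_no_forested_catchment_errors(self):
        coast, catchments = _three_catchments()
        for c in catchments:
            c.forest_fraction = 0.0
        with pytest.raises(ValueError, match="forested"):
            assign_catchments([Point(50, 150)], catchments, coast)


class TestDistanceDecay:
    def test_deposit_on_mouth(self):
        res = distance_decay([Point(0, 0)], [100.0], [Point(0, 0)])
        assert res.distances_km[0] == 0.0
        assert res.fraction_within(1.0) == 1.0

    def test_three_four_five(self):
        res = distance_decay([Point(300_000, 400_000)], [50.0], [Point(0, 0)])
        assert res.distances_km[0] == pytest.approx(500.0)

    def test_nearest_of_several_mouths(self):
        res = distance_decay([Point(90_000, 0)], [1.0], [Point(0, 0), Point(100_000, 0)])
        assert res.distances_km[0] == pytest.approx(10.0)

    def test_curve_is_cumulative_area_fraction(self):
        pts = [Point(1_000, 0), Point(2_000, 0), Point(3_000, 0)]
        res = distance_decay(pts, [10.0, 30.0, 60.0], [Point(0, 0)])
        assert res.fraction_within(1.5) == pytest.approx(0.1)
        assert res.fraction_within(2.5) == pytest.approx(0.4)
        assert res.fraction_within(10.0) == 1.0

    def test_no_mouths_rejected(self):
        with pytest.raises(ValueError):
            distance_decay([Point(0, 0)], [1.0], [])
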