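import math

import numpy as np
import pytest

from conftest import tilted_plane
from oracles import (
    OFFSETS,
    brute_force_accumulation,
    check_directions,
    has_pit,
)
from riversdm import streams as st
from riversdm.grids import ElevationGrid


def random_dem(seed, rows=10, cols=10, cell=30.0):
    rng = np.random.default_rng(seed)
    return ElevationGrid(rng.uniform(0, 100, (rows, cols)), cell_size=cell)


class TestFillSinks:
    def test_pitless_plane_unchanged(self, plane):
        filled = st.fill_sinks(plane)
        np.testing.assert_array_equal(filled.values, plane.values)

    def test_single_pit_raised_to_pour_point(self):
        vals = tilted_plane(7, 7, slope=0.01).values.copy()
        vals[3, 3] -= 5.0
        dem = ElevationGrid(vals, cell_size=100.0)
        filled = st.fill_sinks(dem)
        pour = min(
            vals[3 + dr, 3 + dc] for dr, dc in OFFSETS
        )
        assert filled.values[3, 3] == pytest.approx(pour)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_dem_no_pits(self, seed):
        dem = random_dem(seed, 32, 32)
        filled = st.fill_sinks(dem)
        assert not has_pit(filled.values)
        assert (filled.values >= dem.values - 1e-12).all()

    def test_all_nodata_errors(self):
        dem = ElevationGrid(np.full((4, 4), np.nan), cell_size=10.0)
        with pytest.raises(ValueError):
            st.fill_sinks(dem)


class TestFlowDirection:
    def test_plane_tilted_east_flows_west(self):
        plane = tilted_plane(8, 8, axis="x")  # rises eastward
        flow = st.flow_direction(plane)
        interior = flow.direction[:, 1:]
        assert (interior == 4).all()  # W

    def test_symmetric_ridge_two_fields(self):
        cols = np.concatenate([np.arange(5), np.arange(5)[::-1][1:]])
        vals = np.broadcast_to(cols * 10.0, (6, 9)).copy()
        # break the flat along the crest so it routes deterministically
        flow = st.flow_direction(ElevationGrid(vals, cell_size=100.0))
        assert (flow.direction[:, 1:4] == 4).all()   # west of crest -> W
        assert (flow.direction[:, 5:8] == 0).all()   # east of crest -> E

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        dem = random_dem(seed, 5, 5)
        filled = st.fill_sinks(dem)
        flow = st.flow_direction(filled)
        check_directions(flow.direction, filled.values, filled.cell_size)


class TestFlowAccumulation:
    def test_east_flowing_strip(self):
        vals = np.array([[3.0, 2.0, 1.0]])
        flow = st.flow_direction(ElevationGrid(vals, cell_size=10.0))
        acc = st.flow_accumulation(flow).accumulation
        np.testing.assert_array_equal(acc, [[1, 2, 3]])

    def test_outlet_conservation(self, network_bundle):
        _, flow, _, _ = network_bundle
        total = 0
        nr, nc = flow.shape
        for r in range(nr):
            for c in range(nc):
                if flow.downstream_cell(r, c) is None:
                    total += flow.accumulation[r, c]
        assert total == nr * nc

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_reachability_oracle(self, seed):
        dem = random_dem(seed, 8, 8)
        filled = st.fill_sinks(dem)
        flow = st.flow_accumulation(st.flow_direction(filled))
        expected = brute_force_accumulation(flow.direction)
        np.testing.assert_array_equal(flow.accumulation, expected)

    def test_cycle_detection(self):
        direction = np.array([[0, 4]])  # two cells pointing at each other
        flow = st.FlowGrid(direction=direction, cell_size=10.0)
        with pytest.raises(ValueError, match="cycle"):
            st.flow_accumulation(flow)


class TestExtractStreams:
    def test_threshold_arithmetic(self):
        # 100 m cells: 0.01 km^2 each, 0.1 km^2 -> accumulation >= 10
        direction = np.zeros((1, 15), dtype=int)
        direction[0, -1] = st.OUTLET
        flow = st.FlowGrid(direction=direction, cell_size=100.0)
        flow = st.flow_accumulation(flow)
        mask = st.extract_streams(flow, 0.1)
        assert mask.sum() == 6  # cells with accumulation 10..15

    def test_threshold_larger_than_basin(self, network_bundle):
        _, flow, _, _ = network_bundle
        nr, nc = flow.shape
        area = nr * nc * flow.cell_size ** 2 / 1e6
        assert st.extract_streams(flow, area * 2).sum() == 0

    def test_tilted_plane_count_matches_enumeration(self):
        plane = tilted_plane(20, 20, cell=30.0)
        flow = st.flow_accumulation(st.flow_direction(plane))
        mask = st.extract_streams(flow, 0.1)
        expected = int((flow.accumulation * 30.0 ** 2 / 1e6 >= 0.1).sum())
        assert mask.sum() == expected

    def test_invalid_threshold(self, network_bundle):
        _, flow, _, _ = network_bundle
        with pytest.raises(ValueError):
            st.extract_streams(flow, 0.0)


def straight_strip_network(n_cells, cell=100.0, target=100.0):
    """Single west-flowing stream of n_cells cells, all masked."""
    vals = np.broadcast_to(np.arange(n_cells) * 1.0, (1, n_cells)).copy()
    flow = st.flow_accumulation(
        st.flow_direction(ElevationGrid(vals, cell_size=cell))
    )
    mask = np.ones((1, n_cells), dtype=bool)
    return st.segment_reaches(mask, flow, target)


class TestSegmentReaches:
    def test_1000m_link_gives_10_reaches(self):
        net = straight_strip_network(11)  # 10 inter-cell steps = 1000 m
        assert len(net) == 10
        for reach in net.reaches.values():
            assert reach.length == pytest.approx(100.0)

    def test_1050m_link_merges_remainder(self):
        # 1050 m link: 10 full 100 m pieces + 50 m remainder -> merged
        net = straight_strip_network(22, cell=50.0, target=100.0)
        # 21 steps x 50 m = 1050 m
        lengths = sorted(r.length for r in net.reaches.values())
        assert len(net) == 10
        assert lengths[-1] == pytest.approx(150.0)
        assert all(l == pytest.approx(100.0) for l in lengths[:-1])

    def test_remainder_above_half_kept(self):
        # 21 steps x 55 m = 1155 m: remainder 55 > 50 stays its own reach
        net = straight_strip_network(22, cell=55.0, target=100.0)
        lengths = sorted(r.length for r in net.reaches.values())
        assert len(net) == 12
        assert lengths[0] == pytest.approx(55.0)

    def test_empty_mask_errors(self, network_bundle):
        _, flow, _, _ = network_bundle
        with pytest.raises(ValueError):
            st.segment_reaches(np.zeros(flow.shape, dtype=bool), flow)

    def test_cells_partition(self, network_bundle):
        _, _, mask, net = network_bundle
        seen = {}
        for rid, reach in net.reaches.items():
            for cell in reach.cells:
                assert cell not in seen, "cell assigned twice"
                seen[cell] = rid
        assert len(seen) == int(mask.sum())

    def test_junction_reach_count_matches_tracer(self, network_bundle):
        _, flow, mask, net = network_bundle
        # independent link tracer: count links and their lengths, then apply
        # the cut rule arithmetically
        down = {}
        cells = [(r, c) for r, c in zip(*np.nonzero(mask))]
        cellset = set(cells)
        inflows = {cell: 0 for cell in cells}
        for cell in cells:
            ds = flow.downstream_cell(*cell)
            if ds in cellset:
                inflows[ds] += 1
        expected = 0
        for start in cells:
            if inflows[start] == 1:
                continue
            # walk the link
            length = 0.0
            cur = start
            while True:
                ds = flow.downstream_cell(*cur)
                if ds is None or ds not in cellset:
                    break
                step = flow.cell_size * (
                    math.sqrt(2) if (ds[0] != cur[0] and ds[1] != cur[1]) else 1.0
                )
                length += step
                if inflows[ds] >= 2:
                    break
                cur = ds
            if length <= 0:
                expected += 1
                continue
            n_full = int(length // 100.0)
            rem = length - n_full * 100.0
            if n_full == 0:
                expected += 1
            else:
                expected += n_full + (1 if rem > 50.0 + 1e-9 else 0)
        assert len(net) == expected

    def test_topology_is_forest(self, network_bundle):
        _, _, _, net = network_bundle
        for rid, reach in net.reaches.items():
            seen = {rid}
            cur = reach.downstream_reach
            while cur is not None:
                assert cur not in seen, "cycle in reach topology"
                seen.add(cur)
                cur = net.reaches[cur].downstream_reach


class TestStrahler:
    def _net_from_chain(self, downstream):
        reaches = {
            rid: st.Reach(id=rid, vertices=np.zeros((2, 2)), cells=[],
                          length=100.0, downstream_reach=ds)
            for rid, ds in downstream.items()
        }
        return st.StreamNetwork(reaches=reaches, cell_size=100.0)

    def test_single_path_all_one(self):
        net = self._net_from_chain({0: 1, 1: 2, 2: None})
        assert set(st.strahler_order(net).values()) == {1}

    def test_two_order1_join_makes_2(self):
        net = self._net_from_chain({0: 2, 1: 2, 2: None})
        assert st.strahler_order(net)[2] == 2

    def test_order2_plus_order1_stays_2(self):
        net = self._net_from_chain({0: 2, 1: 2, 2: 4, 3: 4, 4: None})
        order = st.strahler_order(net)
        assert order[2] == 2 and order[3] == 1 and order[4] == 2

    def test_monotone_downstream(self, network_bundle):
        _, _, _, net = network_bundle
        for reach in net.reaches.values():
            if reach.downstream_reach is not None:
                assert (net.reaches[reach.downstream_reach].strahler
                        >= reach.strahler)


class TestReachGeometry:
    def test_straight_reach_sinuosity_one(self):
        reach = st.Reach(id=0, vertices=np.array([[0.0, 0.0], [100.0, 0.0]]),
                         cells=[(0, 0)], length=100.0)
        reach._mid_cell = (0, 0)
        dem = tilted_plane(3, 3)
        st.reach_geometry_attributes(reach, dem)
        assert reach.sinuosity == pytest.approx(1.0)

    def test_semicircle_sinuosity(self):
        theta = np.linspace(0, np.pi, 200)
        radius = 50.0
        verts = np.column_stack([radius * np.cos(theta) + 100.0,
                                 radius * np.sin(theta) + 100.0])
        reach = st.Reach(id=0, vertices=verts, cells=[(1, 1)],
                         length=np.pi * radius)
        reach._mid_cell = (1, 1)
        dem = tilted_plane(5, 5)
        st.reach_geometry_attributes(reach, dem)
        assert reach.sinuosity == pytest.approx(np.pi / 2, rel=1e-3)

    def test_gradient_two_percent(self):
        # 100 m reach dropping 2 m between its endpoint cells
        vals = np.array([[4.0, 2.0, 0.0]])
        dem = ElevationGrid(vals, cell_size=100.0)
        reach = st.Reach(id=0, vertices=np.array([[50.0, 50.0], [150.0, 50.0]]),
                         cells=[(0, 0), (0, 1)], length=100.0)
        reach._mid_cell = (0, 1)
        st.reach_geometry_attributes(reach, dem)
        assert reach.gradient == pytest.approx(2.0)

    def test_gradient_floored_at_zero(self):
        vals = np.array([[0.0, 1.0, 2.0]])
        dem = ElevationGrid(vals, cell_size=100.0)
        reach = st.Reach(id=0, vertices=np.array([[50.0, 50.0], [150.0, 50.0]]),
                         cells=[(0, 0)], length=100.0)
        reach._mid_cell = (0, 0)
        st.reach_geometry_attributes(reach, dem)
        assert reach.gradient == 0.0

    def test_aspect_of_east_rising_plane_points_west(self):
        dem = tilted_plane(5, 5, axis="x")
        reach = st.Reach(id=0, vertices=np.array([[250.0, 250.0], [350.0, 250.0]]),
                         cells=[(2, 2)], length=100.0)
        reach._mid_cell = (2, 2)
        st.reach_geometry_attributes(reach, dem)
        assert reach.aspect == pytest.approx(270.0)

    def test_degenerate_errors(self):
        reach = st.Reach(id=0, vertices=np.array([[0.0, 0.0]]), cells=[],
                         length=0.0)
        with pytest.raises(ValueError):
            st.reach_geometry_attributes(reach, tilted_plane(3, 3))


class TestValleyConfinement:
    def _reach_at(self, row, col, cell=100.0):
        reach = st.Reach(id=0, vertices=np.zeros((2, 2)), cells=[(row, col)],
                         length=100.0)
        reach._mid_cell = (row, col)
        return reach

    def test_flat_plain_zero(self):
        dem = ElevationGrid(np.zeros((9, 9)), cell_size=100.0)
        idx = st.valley_confinement(self._reach_at(4, 4), dem, 300.0, 10.0)
        assert idx == 0.0

    def test_slot_canyon_near_one(self):
        vals = np.full((9, 9), 500.0)
        vals[:, 4] = 0.0  # 1-cell-wide slot
        dem = ElevationGrid(vals, cell_size=100.0)
        idx = st.valley_confinement(self._reach_at(4, 4), dem, 300.0, 10.0)
        # only the 7 slot cells within radius are low; 37 cells in window
        assert idx > 0.75

    def test_v_valley_matches_enumeration(self):
        cols = np.abs(np.arange(11) - 5) * 30.0
        vals = np.broadcast_to(cols, (11, 11)).copy()
        dem = ElevationGrid(vals, cell_size=100.0)
        reach = self._reach_at(5, 5)
        idx = st.valley_confinement(reach, dem, 300.0, 40.0)
        # brute force: window cells within 300 m of (5,5)
        low = total = 0
        for r in range(11):
            for c in range(11):
                if math.hypot(r - 5, c - 5) * 100.0 <= 300.0:
                    total += 1
                    if vals[r, c] <= vals[5, 5] + 40.0:
                        low += 1
        assert idx == pytest.approx(1.0 - low / total)

    def test_radius_below_cell_errors(self):
        dem = ElevationGrid(np.zeros((5, 5)), cell_size=100.0)
        with pytest.raises(ValueError):
            st.valley_confinement(self._reach_at(2, 2), dem, 50.0, 10.0)


class TestNetworkDistances:
    def test_outlet_reach_base_case(self, network_bundle):
        _, _, _, net = network_bundle
        for rid in net.outlets():
            reach = net.reaches[rid]
            assert reach.dist_downstream == pytest.approx(reach.length / 1000.0)

    def test_linear_chain(self):
        net = straight_strip_network(11)  # 10 x 100 m chain
        st.network_distances(net)
        headwater = [r for r in net.reaches.values()
                     if all(o.downstream_reach != r.id
                            for o in net.reaches.values())]
        assert len(headwater) == 1
        assert headwater[0].dist_downstream == pytest.approx(1.0)

    def test_branched_matches_brute_force(self, network_bundle):
        _, _, _, net = network_bundle
        up = net.upstream_map()

        def dfs_down(rid):
            reach = net.reaches[rid]
            if reach.downstream_reach is None:
                return reach.length
            return reach.length + dfs_down(reach.downstream_reach)

        def dfs_up(rid):
            reach = net.reaches[rid]
            ups = up[rid]
            if not ups:
                return reach.length
            return reach.length + max(dfs_up(u) for u in ups)

        ids = sorted(net.reaches)[::7]  # sample for speed
        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(10000)
        try:
            for rid in ids:
                assert net.reaches[rid].dist_downstream == pytest.approx(
                    dfs_down(rid) / 1000.0)
                assert net.reaches[rid].dist_upstream == pytest.approx(
                    dfs_up(rid) / 1000.0)
        finally:
            sys.setrecursionlimit(old)


class TestCatchments:
    def test_tilted_plane_headwater_strip(self):
        plane = tilted_plane(6, 12, axis="x")  # flows west along rows
        flow = st.flow_accumulation(st.flow_direction(plane))
        reach = st.Reach(id=0, vertices=np.zeros((2, 2)), cells=[(2, 5)],
                        length=100.0)
        catchment = st.delineate_catchment(reach, flow)
        assert catchment == {(2, c) for c in range(5, 12)}

    def test_outlet_catchment_is_whole_basin(self, network_bundle):
        _, flow, _, net = network_bundle
        sizes = 0
        for rid in net.outlets():
            sizes += len(st.delineate_catchment(net.reaches[rid], flow))
        # outlet catchments tile the grid cells that drain through streams;
        # together with non-stream outlet cells they cover everything once
        nr, nc = flow.shape
        assert sizes <= nr * nc
        big = max(len(st.delineate_catchment(net.reaches[rid], flow))
                  for rid in net.outlets())
        assert big > 100

    def test_catchment_area_equals_drainage_area(self, network_bundle):
        _, flow, _, net = network_bundle
        cell_km2 = flow.cell_size ** 2 / 1e6
        for rid in sorted(net.reaches)[::11]:
            reach = net.reaches[rid]
            catchment = st.delineate_catchment(reach, flow)
            assert len(catchment) * cell_km2 == pytest.approx(
                reach.drainage_area)

    def test_nesting_downstream(self, network_bundle):
        _, flow, _, net = network_bundle
        for rid in sorted(net.reaches)[::17]:
            reach = net.reaches[rid]
            if reach.downstream_reach is None:
                continue
            mine = st.delineate_catchment(reach, flow)
            below = st.delineate_catchment(
                net.reaches[reach.downstream_reach], flow)
            assert mine <= below


class TestWeightedAccumulation:
    def test_uniform_weights_equal_accumulation(self, network_bundle):
        _, flow, _, _ = network_bundle
        acc = st.flow_accumulate_weights(flow, np.ones(flow.shape))
        np.testing.assert_allclose(acc, flow.accumulation)

    def test_matches_catchment_enumeration(self, network_bundle):
        _, flow, _, net = network_bundle
        rng = np.random.default_rng(5)
        field = rng.uniform(0, 10, flow.shape)
        acc = st.flow_accumulate_weights(flow, field)
        for rid in sorted(net.reaches)[::23]:
            reach = net.reaches[rid]
            catchment = st.delineate_catchment(reach, flow)
            r, c = reach.anchor_cells[-1]
            expected = sum(field[cell] for cell in catchment)
            assert acc[r, c] == pytest.approx(expected)


class TestRoutingPropertySmallGrids:
    @pytest.mark.parametrize("seed", range(10))
    def test_routing_equals_brute_force_12x12(self, seed):
        dem = random_dem(seed, 12, 12)
        filled = st.fill_sinks(dem)
        flow = st.flow_accumulation(st.flow_direction(filled))
        check_directions(flow.direction, filled.values, filled.cell_size)
        np.testing.assert_array_equal(
            flow.accumulation, brute_force_accumulation(flow.direction))
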