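"""Dispersal kernel math, least-cost tables and network assembly."""

import math

import numpy as np
import pytest

from habnet.network import (
    DispersalParams,
    build_network,
    cost_threshold,
    d0_for_max_distance,
    edge_probability,
    interpatch_costs,
)
from habnet.patches import Patch, PatchSet
from habnet.rasters import Raster

from conftest import make_patchset


class TestKernelMath:
    @pytest.mark.parametrize(
        "max_dist,d0",
        [(1500, 113), (4000, 301), (4411, 332), (2658, 200)],
    )
    def test_species_specific_d0_values(self, max_dist, d0):
        # literature maximum dispersal distances and their kernel scales
        assert d0_for_max_distance(max_dist) == d0

    def test_pelophylax_rounding_discrepancy(self):
        # 1760 * log(0.5)/log(1e-4) = 132.45: nearest-integer gives 132,
        # one unit off the published 133
        assert d0_for_max_distance(1760) == 132

    def test_cost_threshold_of_alytes_kernel(self):
        t = cost_threshold(DispersalParams(d0=113))
        assert t == pytest.approx(1501.5, abs=0.05)

    def test_prob_min_equal_p_recovers_d0(self):
        t = cost_threshold(DispersalParams(d0=100, p=0.5, prob_min=0.5))
        assert t == pytest.approx(100)

    def test_squared_probability_doubles_cost(self):
        t = cost_threshold(DispersalParams(d0=100, p=0.5, prob_min=0.25))
        assert t == pytest.approx(200)

    @pytest.mark.parametrize("k", [50, 113, 200, 332, 1000])
    def test_round_trip_identity(self, k):
        t = cost_threshold(DispersalParams(d0=k))
        assert d0_for_max_distance(t) == k

    def test_round_trip_error_bounded_on_distance_grid(self):
        for dist in (300, 1000, 2000, 4000, 6000, 8000, 10000):
            d0 = d0_for_max_distance(dist)
            back = cost_threshold(DispersalParams(d0=d0))
            assert abs(back - dist) <= 7.0

    def test_edge_probability_values(self):
        params = DispersalParams(d0=200)
        assert edge_probability(0.0, params) == pytest.approx(1.0)
        assert edge_probability(200.0, params) == pytest.approx(0.5)
        assert edge_probability(400.0, params) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            edge_probability(-1.0, params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DispersalParams(d0=100, p=1.0)
        with pytest.raises(ValueError):
            DispersalParams(d0=100, prob_min=0.0)
        with pytest.raises(ValueError):
            d0_for_max_distance(-5)


def grid_patchset(labels, cell_size=1.0):
    labels = np.asarray(labels, dtype=int)
    patches = []
    for pid in np.unique(labels):
        if pid == 0:
            continue
        rr, cc = np.nonzero(labels == pid)
        patches.append(
            Patch(pid, rr, cc, area=float(len(rr) * cell_size**2), hsi=0.5)
        )
    return PatchSet(patches=patches, labels=labels, cell_size=cell_size,
                    origin=(0.0, labels.shape[0] * cell_size))


class TestInterpatchCosts:
    def test_adjacent_patches_grid_cost_one_step(self):
        labels = np.array([[1, 2]])
        ps = grid_patchset(labels, cell_size=10.0)
        costs = interpatch_costs(ps, cost_cap=100.0, mode="grid")
        assert costs[(1, 2)] == pytest.approx(10.0)

    def test_single_cell_patches_euclidean_distance(self):
        labels = np.zeros((1, 6), dtype=int)
        labels[0, 0], labels[0, 5] = 1, 2
        ps = grid_patchset(labels, cell_size=10.0)
        costs = interpatch_costs(ps, cost_cap=1000.0, mode="euclidean")
        # centres 50 m apart; cell squares are 10 m wide, so the polygon
        # boundary gap is 40 m
        assert costs[(1, 2)] == pytest.approx(40.0)
        gi = ps.geometry(ps[0])
        gj = ps.geometry(ps[1])
        assert costs[(1, 2)] == pytest.approx(gi.distance(gj))

    def test_grid_cost_dominates_euclidean_on_uniform_surface(self):
        rng = np.random.default_rng(4)
        labels = np.zeros((20, 20), dtype=int)
        cells = rng.choice(400, size=8, replace=False)
        for pid, cell in enumerate(cells, start=1):
            labels[cell // 20, cell % 20] = pid
        ps = grid_patchset(labels, cell_size=5.0)
        eu = interpatch_costs(ps, cost_cap=1e4, mode="euclidean")
        gr = interpatch_costs(ps, cost_cap=1e4, mode="grid")
        for pair, d_eu in eu.items():
            assert gr[pair] >= d_eu - 1e-9

    def test_grid_cost_within_octile_bound_of_center_distance(self):
        labels = np.zeros((30, 30), dtype=int)
        labels[2, 3] = 1
        labels[20, 25] = 2
        ps = grid_patchset(labels, cell_size=1.0)
        gr = interpatch_costs(ps, cost_cap=1e4, mode="grid")
        center_dist = math.hypot(20 - 2, 25 - 3)
        assert gr[(1, 2)] <= center_dist * 1.0824 + 1e-9

    def test_untraversable_cells_block_grid_paths(self):
        labels = np.zeros((1, 5), dtype=int)
        labels[0, 0], labels[0, 4] = 1, 2
        ps = grid_patchset(labels, cell_size=1.0)
        res = np.ones((1, 5))
        res[0, 2] = np.inf
        costs = interpatch_costs(ps, cost_cap=100.0, resistance=res, mode="grid")
        assert (1, 2) not in costs

    def test_resistance_scales_grid_cost(self):
        labels = np.zeros((1, 5), dtype=int)
        labels[0, 0], labels[0, 4] = 1, 2
        ps = grid_patchset(labels, cell_size=1.0)
        flat = interpatch_costs(ps, cost_cap=100.0, mode="grid")
        res = np.full((1, 5), 3.0)
        hard = interpatch_costs(ps, cost_cap=100.0, resistance=res, mode="grid")
        assert hard[(1, 2)] == pytest.approx(3.0 * flat[(1, 2)])

    def test_empty_patchset_gives_empty_table(self):
        ps = grid_patchset(np.zeros((3, 3), dtype=int))
        assert interpatch_costs(ps, cost_cap=10.0) == {}


class TestBuildNetwork:
    def _params_for_threshold(self, threshold):
        # choose d0 so that the kernel's cost threshold equals `threshold`
        d0 = threshold * math.log(0.5) / math.log(1e-4)
        return DispersalParams(d0=d0)

    def test_toy_costs_filtered_by_threshold(self):
        ps = make_patchset([(1, 1.0, 0.5), (2, 1.0, 0.5), (3, 1.0, 0.5), (4, 1.0, 0.5)])
        costs = {(1, 2): 100.0, (1, 3): 250.0, (2, 3): 300.0, (1, 4): 900.0}
        net = build_network(ps, costs, self._params_for_threshold(260.0))
        assert set(map(frozenset, net.edges)) == {frozenset({1, 2}), frozenset({1, 3})}

    def test_tiny_d0_gives_no_edges(self):
        ps = make_patchset([(1, 1.0, 0.5), (2, 1.0, 0.5)])
        net = build_network(ps, {(1, 2): 100.0}, DispersalParams(d0=1.0))
        assert len(net.edges) == 0

    def test_huge_threshold_gives_complete_graph(self, default_study):
        ps = default_study["patches"]
        costs = default_study["costs"]
        # cap was 10 km; restrict to pairs below 5 km and use a 5 km threshold
        sub = {k: v for k, v in costs.items() if v < 5000.0}
        net = build_network(ps, sub, self._params_for_threshold(5000.0))
        assert len(net.edges) == len(sub)

    def test_edge_attributes_satisfy_kernel(self, default_study):
        params = DispersalParams(d0=301)
        net = build_network(
            default_study["patches"], default_study["costs"], params
        )
        thr = cost_threshold(params)
        for _, _, d in net.edges(data=True):
            assert d["cost"] < thr
            assert d["probability"] == pytest.approx(
                edge_probability(d["cost"], params)
            )
            assert params.prob_min <= d["probability"] <= 1.0

    def test_edge_monotonicity_in_threshold(self, default_study):
        ps = default_study["patches"]
        costs = default_study["costs"]
        prev_edges = None
        for dist in (300, 1000, 2000, 4000, 6000, 8000, 10000):
            params = DispersalParams(d0=d0_for_max_distance(dist))
            net = build_network(ps, costs, params, max_dispersal_distance=dist)
            edges = set(map(frozenset, net.edges))
            if prev_edges is not None:
                assert prev_edges <= edges
            prev_edges = edges
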