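"""Synthetic-landscape generator: determinism, geometry and sampling laws."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from habnet import synthetic as syn
from habnet.network import DispersalParams, build_network
from habnet.patches import PatchSet

from conftest import build_study, make_patchset


class TestSuitability:
    def test_deterministic_given_seed(self):
        cfg = syn.LandscapeConfig(seed=42, grid_width=64, grid_height=64)
        a = syn.generate_suitability(cfg)
        b = syn.generate_suitability(cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_values_in_unit_interval(self):
        for seed in (0, 1, 2):
            r = syn.generate_suitability(
                syn.LandscapeConfig(seed=seed, grid_width=64, grid_height=64)
            )
            assert r.data.min() >= 0.0 and r.data.max() <= 1.0

    def test_zero_correlation_length_gives_iid_noise(self):
        cfg = syn.LandscapeConfig(
            seed=3, grid_width=256, grid_height=256,
            suitability_correlation_length=0.0,
        )
        f = syn.generate_suitability(cfg).data.astype(float)
        r_lag1 = np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]
        assert abs(r_lag1) < 0.05

    def test_smoothing_induces_autocorrelation(self):
        cfg = syn.LandscapeConfig(seed=3, grid_width=256, grid_height=256)
        f = syn.generate_suitability(cfg).data.astype(float)
        r_lag1 = np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]
        assert r_lag1 > 0.9

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            syn.LandscapeConfig(grid_width=8, grid_height=64)


class TestMask:
    def test_no_sites_all_false(self):
        cfg = syn.LandscapeConfig(seed=5, grid_width=64, grid_height=64, n_water_sites=0)
        assert syn.generate_mask(cfg).data.sum() == 0

    def test_zero_buffer_is_point_mask(self):
        cfg = syn.LandscapeConfig(
            seed=5, grid_width=64, grid_height=64, n_water_sites=10, water_buffer=0.0
        )
        assert 0 < syn.generate_mask(cfg).data.sum() <= 10

    def test_buffered_mask_matches_disc_rasterization(self):
        # oracle: brute-force distance from every cell centre to every site
        cfg = syn.LandscapeConfig(
            seed=7, grid_width=64, grid_height=64, cell_size=10.0,
            n_water_sites=3, water_buffer=20.0,
        )
        mask = syn.generate_mask(cfg).data.astype(bool)
        sites = syn.water_sites(cfg)
        h = cfg.grid_height * cfg.cell_size
        rr, cc = np.mgrid[0:64, 0:64]
        cx = (cc + 0.5) * cfg.cell_size
        cy = h - (rr + 0.5) * cfg.cell_size
        expected = np.zeros((64, 64), dtype=bool)
        for px, py in sites:
            expected |= (cx - px) ** 2 + (cy - py) ** 2 <= cfg.water_buffer**2
            expected[
                min(int((h - py) // cfg.cell_size), 63),
                min(int(px // cfg.cell_size), 63),
            ] = True
        np.testing.assert_array_equal(mask, expected)


class TestTrueOccupancy:
    def _edgeless_net(self, patches):
        g = nx.Graph()
        for p in patches:
            g.add_node(p.patch_id, area=p.area, hsi=p.hsi)
        return g

    def test_saturated_logistic_occupies_everything(self):
        patches = make_patchset([(i, 1e4, 0.5) for i in range(1, 21)])
        cfg = syn.OccupancyTruthConfig(
            intercept=50.0, beta_hsi=0.0, beta_logarea=0.0, beta_connectivity=0.0, seed=0
        )
        occ = syn.generate_true_occupancy(patches, self._edgeless_net(patches), cfg)
        assert all(occ.values())

    def test_rate_matches_logistic_mean_without_connectivity(self):
        # Monte-Carlo oracle: with beta_connectivity = 0 the patches are
        # independent Bernoulli(sigmoid(eta)) draws.
        rng = np.random.default_rng(0)
        hsi = rng.uniform(0, 1, 1500)
        patches = make_patchset([(i + 1, 1e4, h) for i, h in enumerate(hsi)])
        cfg = syn.OccupancyTruthConfig(
            intercept=-1.0, beta_hsi=2.0, beta_logarea=0.0,
            beta_connectivity=0.0, seed=11,
        )
        occ = syn.generate_true_occupancy(patches, self._edgeless_net(patches), cfg)
        p = 1.0 / (1.0 + np.exp(-(-1.0 + 2.0 * hsi)))
        rate = np.mean(list(occ.values()))
        se = np.sqrt(np.sum(p * (1 - p))) / len(p)
        assert abs(rate - p.mean()) < 3 * se

    def test_connectivity_favours_connected_patches(self):
        # over replicate seeds, occupied patches are better connected
        diffs = []
        for seed in range(20):
            study = build_study(
                landscape_seed=2, occupancy_seed=seed,
                grid_width=96, grid_height=96, n_water_sites=250,
            )
            net = study["truth_net"]
            occ = study["occupancy"]
            deg = dict(net.degree())
            occ_deg = [deg[i] for i, o in occ.items() if o]
            un_deg = [deg[i] for i, o in occ.items() if not o]
            if occ_deg and un_deg:
                diffs.append(np.mean(occ_deg) - np.mean(un_deg))
        assert np.mean(diffs) > 0

    def test_patch_network_mismatch_rejected(self):
        patches = make_patchset([(1, 1e4, 0.5), (2, 1e4, 0.5)])
        g = nx.Graph()
        g.add_node(99, area=1e4, hsi=0.5)
        with pytest.raises(ValueError):
            syn.generate_true_occupancy(patches, g, syn.OccupancyTruthConfig())


class TestObservations:
    def _patchset(self, n):
        return make_patchset([(i + 1, 1e4, 0.5) for i in range(n)], cell_size=100.0)

    @staticmethod
    def _patch_of(obs, patches):
        rows = ((patches.origin[1] - obs["y"]) // patches.cell_size).astype(int)
        cols = ((obs["x"] - patches.origin[0]) // patches.cell_size).astype(int)
        return patches.labels[rows, cols]

    def test_perfect_detection_records_every_visited_occupied_patch(self):
        patches = self._patchset(200)
        occupancy = {p.patch_id: True for p in patches}
        cfg = syn.SamplingConfig(detection_prob_per_visit=1.0, seed=3)
        obs = syn.generate_observations(patches, occupancy, cfg)
        obs = obs.assign(patch_id=self._patch_of(obs, patches))
        visited = set(obs["patch_id"])
        with_focal = set(obs.loc[obs["species"] == "focal", "patch_id"])
        assert visited == with_focal

    def test_unoccupied_patches_yield_no_focal_records(self):
        patches = self._patchset(100)
        occupancy = {p.patch_id: False for p in patches}
        obs = syn.generate_observations(patches, occupancy, syn.SamplingConfig(seed=3))
        assert (obs["species"] != "focal").all()

    def test_no_focal_records_at_unoccupied_patches(self, default_study):
        obs = default_study["observations"]
        patches = default_study["patches"]
        occ = default_study["occupancy"]
        focal = obs[obs["species"] == "focal"]
        x0, y0 = patches.origin
        cs = patches.cell_size
        for _, r in focal.iterrows():
            row = int((y0 - r.y) // cs)
            col = int((r.x - x0) // cs)
            pid = patches.labels[row, col]
            assert pid != 0 and occ[pid]

    def test_detection_fraction_matches_binomial(self):
        # closed form: P(>=1 focal record | occupied, v visits) = 1-(1-p)^v
        p = 0.6
        patches = self._patchset(1500)
        occupancy = {pp.patch_id: True for pp in patches}
        cfg = syn.SamplingConfig(
            mean_visits_per_patch=3.0, detection_prob_per_visit=p, seed=9
        )
        obs = syn.generate_observations(patches, occupancy, cfg)
        x0, y0 = patches.origin
        cs = patches.cell_size
        rowidx = ((y0 - obs["y"]) // cs).astype(int)
        obs = obs.assign(patch_id=patches.labels[rowidx, 0])
        visits = obs.groupby("patch_id")["date"].nunique()
        focal = obs[obs["species"] == "focal"].groupby("patch_id")["date"].nunique()
        for v in (2, 3):
            ids = visits.index[visits == v]
            if len(ids) < 50:
                continue
            frac = np.mean([focal.get(i, 0) > 0 for i in ids])
            expect = 1 - (1 - p) ** v
            se = np.sqrt(expect * (1 - expect) / len(ids))
            assert abs(frac - expect) < max(3 * se, 0.02)

    def test_records_inside_patches_and_determinism(self, default_study):
        obs = default_study["observations"]
        patches = default_study["patches"]
        x0, y0 = patches.origin
        cs = patches.cell_size
        rows = ((y0 - obs["y"]) // cs).astype(int)
        cols = ((obs["x"] - x0) // cs).astype(int)
        assert (patches.labels[rows, cols] > 0).all()
        obs2 = syn.generate_observations(
            patches, default_study["occupancy"], syn.SamplingConfig(seed=1)
        )
        pd.testing.assert_frame_equal(obs, obs2)
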