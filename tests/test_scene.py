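"""Synthetic scene generator: planning, dynamics, rendering, ground truth."""

import math

import numpy as np
import pandas as pd
import pytest

from moca import occupancy as occ
from moca import scene as sc


def _noiseless():
    return sc.RenderParams(noise_sd=0.0)


class TestLayout:
    def test_defaults(self):
        lay = sc.DropletLayout()
        assert lay.n_droplets == 24
        assert lay.spot_radius_px == pytest.approx(159.0)
        h, w = lay.frame_shape
        assert h == w and h % 2 == 1
        assert h >= lay.spot_diameter_mm * lay.pixels_per_mm  # covers the droplet

    def test_invariants(self):
        with pytest.raises(ValueError):
            sc.DropletLayout(n_rows=0)
        with pytest.raises(ValueError):
            sc.DropletLayout(pitch_mm=1.0)  # smaller than the spot

    def test_positions_roundtrip(self):
        lay = sc.DropletLayout()
        for did in range(lay.n_droplets):
            r, c = lay.position(did)
            assert lay.droplet_id(r, c) == did


class TestPlanExperiment:
    def test_reference_design_grouping(self, default_scene):
        assert len(default_scene.droplets) == 24
        groups = [d.group for d in default_scene.droplets]
        assert groups == [1000.0] * 6 + [100.0] * 6 + [10.0] * 6 + [1.0] * 6

    def test_capacity_mismatch(self):
        with pytest.raises(sc.ConfigurationError):
            sc.plan_experiment(sc.DropletLayout(), [1000, 1], 6, 1.0)

    def test_zero_concentration_all_empty(self):
        syn = sc.plan_experiment(sc.DropletLayout(), [0.0], 24, 1.0, seed=1)
        assert all(d.cell_count == 0 for d in syn.droplets)

    def test_single_occupancy_rate_matches_poisson(self):
        # mean number of singly occupied droplets over replicate 36-droplet
        # plans at 0.25 cells/droplet approaches 36 * 0.19470 = 7.009
        lay = sc.DropletLayout(n_rows=6, n_cols=6)
        n_rep = 300
        singles = []
        for s in range(n_rep):
            syn = sc.plan_experiment(lay, [0.25], 36, 1.0, seed=10_000 + s)
            singles.append(sum(d.cell_count == 1 for d in syn.droplets))
        expected = 36 * occ.occupancy_pmf(1, 0.25)
        sd_one = math.sqrt(36 * 0.1947 * (1 - 0.1947))
        assert abs(np.mean(singles) - expected) <= 3 * sd_one / math.sqrt(n_rep)


class TestBiomassDynamics:
    def test_empty_droplet(self):
        traj = sc.simulate_biomass(0, [], sc.GrowthParams(), sc.default_times(12))
        assert traj.shape == (0, 25)

    def test_exponential_closed_form(self):
        # K -> infinity, no lag: b(t) = b0 exp(mu t)
        p = sc.GrowthParams(lag_mean_h=0.0, lag_sd_h=0.0, carrying_capacity=1e12)
        times = sc.default_times(24.0, 0.5)
        traj = sc.simulate_biomass(1, [0.0], p, times)
        expected = p.initial_biomass_per_cell * np.exp(p.specific_growth_rate * times)
        assert np.allclose(traj[0], expected, rtol=0.01)

    def test_equal_lags_stay_symmetric(self):
        p = sc.GrowthParams(lag_mean_h=2.0, lag_sd_h=0.0)
        traj = sc.simulate_biomass(2, [2.0, 2.0], p, sc.default_times(48))
        assert np.array_equal(traj[0], traj[1])

    def test_lagged_cell_holds_initial_biomass(self):
        p = sc.GrowthParams(lag_mean_h=0.0, lag_sd_h=0.0)
        traj = sc.simulate_biomass(1, [10.0], p, sc.default_times(48))
        times = sc.default_times(48)
        assert np.all(traj[0][times <= 10.0] == p.initial_biomass_per_cell)
        assert traj[0][-1] > p.initial_biomass_per_cell

    def test_capacity_conserved(self):
        p = sc.GrowthParams()
        lags = np.random.default_rng(0).uniform(0, 4, size=5)
        traj = sc.simulate_biomass(5, lags, p, sc.default_times(72))
        total = traj.sum(axis=0)
        assert np.all(total <= p.carrying_capacity * (1 + 1e-6))
        # and the population does saturate
        assert total[-1] >= 0.99 * p.carrying_capacity

    def test_mismatched_lags_rejected(self):
        with pytest.raises(ValueError):
            sc.simulate_biomass(2, [0.0], sc.GrowthParams(), sc.default_times(12))


class TestRendering:
    def test_blank_droplet_at_background(self):
        syn = sc.build_scene(
            sc.DropletLayout(n_rows=1, n_cols=1), [0], render=_noiseless(),
            times_h=sc.default_times(2), seed=4
        )
        stack, truth = sc.render_stack(syn)
        lay = syn.layout
        from moca._disks import disk_mask

        mask = disk_mask(lay.frame_shape, lay.frame_center, 0.9 * lay.spot_radius_px)
        expected = syn.render.background_intensity * syn.droplets[0].illumination
        for t in range(stack.shape[1]):
            assert abs(stack[0, t][mask].mean() - expected) <= 0.5  # quantization

    def test_darkening_monotone_before_plateau(self):
        syn = sc.build_scene(
            sc.DropletLayout(n_rows=1, n_cols=2), [1, 3], render=_noiseless(), seed=9
        )
        stack, truth = sc.render_stack(syn)
        from moca._disks import disk_mask

        lay = syn.layout
        mask = disk_mask(lay.frame_shape, lay.frame_center, 0.9 * lay.spot_radius_px)
        for d in range(2):
            pl = truth.plateau_time_h.iloc[d]
            sel = syn.times_h <= pl
            means = stack[d][sel][:, mask].mean(axis=1)
            assert np.all(np.diff(means) <= 0.05)

    def test_sporulation_brightens_after_plateau(self):
        g = sc.GrowthParams(sporulation=True, rebound_fraction=0.3)
        syn = sc.build_scene(
            sc.DropletLayout(n_rows=1, n_cols=1), [2], growth=g, render=_noiseless(), seed=2
        )
        stack, truth = sc.render_stack(syn)
        from moca._disks import disk_mask

        lay = syn.layout
        mask = disk_mask(lay.frame_shape, lay.frame_center, 0.9 * lay.spot_radius_px)
        means = stack[0][:, mask].mean(axis=1)
        i_plateau = int(np.searchsorted(syn.times_h, truth.plateau_time_h.iloc[0]))
        assert means[-1] > means[i_plateau]

    def test_colony_centers_inside_spot(self, default_scene):
        lay = default_scene.layout
        cy, cx = lay.frame_center
        for d in default_scene.droplets:
            if d.cell_count == 0:
                continue
            dist = np.hypot(d.centers_px[:, 0] - cy, d.centers_px[:, 1] - cx)
            assert np.all(dist < lay.spot_radius_px)

    def test_determinism_bit_identical(self):
        args = dict(times_h=sc.default_times(12), seed=21)
        lay = sc.DropletLayout(n_rows=1, n_cols=2)
        s1, t1 = sc.render_stack(sc.build_scene(lay, [1, 2], **args))
        s2, t2 = sc.render_stack(sc.build_scene(lay, [1, 2], **args))
        assert np.array_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)


class TestGroundTruth:
    def test_colonies_distinct_until_half_capacity(self):
        # multi-colony droplets must not merge before total biomass K/2
        g = sc.GrowthParams(lag_sd_h=0.5)
        for seed in (31, 32, 33):
            syn = sc.build_scene(
                sc.DropletLayout(n_rows=1, n_cols=3), [2, 3, 4], growth=g,
                render=_noiseless(), seed=seed
            )
            _, truth = sc.render_stack(syn)
            for _, row in truth.iterrows():
                drop = syn.droplets[int(row.droplet_id)]
                traj = sc.simulate_biomass(
                    drop.cell_count, drop.lags_h, g, syn.times_h
                )
                total = traj.sum(axis=0)
                t_half = syn.times_h[np.searchsorted(total, g.carrying_capacity / 2)]
                # merge may fall in the same frame in which K/2 is crossed
                assert math.isnan(row.merge_time_h) or row.merge_time_h >= t_half

    def test_threshold_time_decreases_log_linearly(self, exponential_results):
        # tenfold more founder cells shifts the crossing ln(10)/mu earlier
        results, _ = exponential_results
        by_group = {r.group: r.threshold_time_h for r in results}
        times = [by_group[g] for g in [1.0, 10.0, 100.0, 1000.0]]
        step = math.log(10) / 0.7
        for a, b in zip(times, times[1:]):
            assert abs((a - b) - step) <= 0.02 * step

    def test_true_crossing_matches_noiseless_rendered_series(self):
        from moca import growth, imaging

        syn = sc.build_scene(
            sc.DropletLayout(n_rows=1, n_cols=2), [1, 3], render=_noiseless(), seed=9
        )
        stack, truth = sc.render_stack(syn)
        rois = imaging.locate_droplets(stack, syn.layout, mode="grid")
        series = imaging.extract_transmission(stack, rois, syn.times_h)
        for s, (_, row) in zip(series, truth.iterrows()):
            norm = growth.normalize_curve(s)
            t = growth.threshold_growth_time(norm, s.times_h)
            assert abs(t - row.true_threshold_time_h) <= syn.substep_h

    def test_dense_rerender_oracle_equivalence(self):
        # crossing from 0.5-h frames (interpolated) vs brute-force dense
        # 0.05-h re-rendering of the same droplet
        from moca import growth, imaging

        lay = sc.DropletLayout(n_rows=1, n_cols=1)

        def crossing(interval):
            syn = sc.build_scene(
                lay, [1], render=_noiseless(),
                times_h=sc.default_times(24.0, interval), seed=17
            )
            stack, _ = sc.render_stack(syn)
            rois = imaging.locate_droplets(stack, lay, mode="grid")
            s = imaging.extract_transmission(stack, rois, syn.times_h)[0]
            return growth.threshold_growth_time(growth.normalize_curve(s), s.times_h)

        assert abs(crossing(0.5) - crossing(0.05)) <= 0.1

    def test_checkpoint_precedes_merge(self, marine_render, marine_scene):
        _, truth = marine_render
        for _, row in truth.iterrows():
            if pd.isna(row.checkpoint_frame):
                continue
            t_cp = marine_scene.times_h[int(row.checkpoint_frame)]
            assert math.isnan(row.merge_time_h) or t_cp < row.merge_time_h


class TestSceneIO:
    def test_roundtrip_identical(self, tmp_path):
        syn = sc.build_scene(
            sc.DropletLayout(n_rows=1, n_cols=2), [0, 2],
            times_h=sc.default_times(6), seed=8
        )
        stack, truth = sc.render_stack(syn)
        sc.write_scene(syn, stack, truth, tmp_path)
        syn2, stack2, truth2 = sc.load_scene(tmp_path)
        assert np.array_equal(stack, stack2)
        assert syn2.seed == syn.seed
        assert len(truth2) == syn.layout.n_droplets
        assert np.allclose(
            syn2.droplets[1].centers_px, syn.droplets[1].centers_px, atol=0.01
        )

    def test_ground_truth_row_count(self, default_render):
        _, truth = default_render
        assert len(truth) == 24
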