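"""Synthetic scene generator: determinism, planted-truth properties,
geometry and linearity."""

import numpy as np
import pytest
from dataclasses import replace

from ecmbridge import (SceneConfig, generate_bridge_scene,
                       generate_cluster_nuclei, generate_fiber_volume,
                       intensity_density)
from ecmbridge.circstats import (axial_distance, axial_mean,
                                 axial_resultant_length)


class TestConfigValidation:
    def test_invalid_fields_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(dead_fraction=1.5)
        with pytest.raises(ValueError):
            SceneConfig(kappa=-1.0)
        with pytest.raises(ValueError):
            SceneConfig(bridge_axis_angle=180.0)
        with pytest.raises(ValueError):
            SceneConfig(cluster_centers_um=[(0, 0, 0), (0, 0, 0)])


class TestFiberVolume:
    def test_zero_density_zero_noise_blank_outside_artefacts(self):
        cfg = SceneConfig(image_shape=(2, 64, 64), fiber_density=0.0,
                          noise_gaussian_sd=0.0, background=0.0,
                          artefact_spots=[(10, 10, 3)], seed=1)
        stack, truth = generate_fiber_volume(cfg)
        outside = ~truth.artefact_mask
        assert np.all(stack.voxels[:, outside] == 0)
        assert stack.voxels[0][truth.artefact_mask].min() > 0

    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(image_shape=(2, 96, 96), fiber_density=3.0,
                          kappa=5.0, seed=11)
        a, _ = generate_fiber_volume(cfg)
        b, _ = generate_fiber_volume(cfg)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_different_seed_differs(self):
        cfg = SceneConfig(image_shape=(2, 96, 96), fiber_density=3.0, seed=11)
        a, _ = generate_fiber_volume(cfg)
        b, _ = generate_fiber_volume(replace(cfg, seed=12))
        assert not np.array_equal(a.voxels, b.voxels)

    def test_isotropic_truth_angles_balanced(self):
        cfg = SceneConfig(image_shape=(8, 360, 360), pixel_size_xy=1.0,
                          fiber_density=100.0, kappa=0.0, seed=2)
        _, truth = generate_fiber_volume(cfg)
        assert len(truth.fiber_segments) > 9000
        assert axial_resultant_length(truth.fiber_angles) < 0.03

    def test_concentrated_truth_mean_recovered(self):
        cfg = SceneConfig(image_shape=(8, 360, 360), pixel_size_xy=1.0,
                          fiber_density=100.0, kappa=50.0,
                          bridge_axis_angle=68.8, seed=2)
        _, truth = generate_fiber_volume(cfg)
        assert axial_distance(axial_mean(truth.fiber_angles), 68.8) < 1.0

    def test_truth_alignment_monotone_in_kappa(self):
        r = []
        for kappa in (0.0, 1.0, 5.0, 50.0):
            cfg = SceneConfig(image_shape=(4, 360, 360), pixel_size_xy=1.0,
                              fiber_density=20.0, kappa=kappa, seed=4)
            _, truth = generate_fiber_volume(cfg)
            r.append(axial_resultant_length(truth.fiber_angles))
        assert r == sorted(r)

    def test_drawn_pixels_scale_linearly_with_density(self):
        sums = []
        for dens in (2.0, 4.0):
            cfg = SceneConfig(image_shape=(6, 256, 256), pixel_size_xy=2.5,
                              fiber_density=dens, noise_gaussian_sd=0.0,
                              background=0.0, seed=6)
            stack, _ = generate_fiber_volume(cfg)
            sums.append(stack.voxels.sum())
        assert sums[1] / sums[0] == pytest.approx(2.0, rel=0.10)


class TestClusterNuclei:
    def test_zero_dead_pi_is_background(self):
        cfg = SceneConfig(image_shape=(9, 96, 96), pixel_size_xy=1.5,
                          z_step=10.0, cells_per_cluster=80,
                          cluster_diameter_um=120.0, dead_fraction=0.0,
                          noise_gaussian_sd=0.0, seed=3)
        _, pi, _ = generate_cluster_nuclei(cfg)
        assert np.all(pi.voxels <= cfg.background)

    @pytest.mark.parametrize("dead_fraction", [0.25, 0.5])
    def test_exact_planted_dead_count(self, dead_fraction):
        cfg = SceneConfig(image_shape=(9, 96, 96), pixel_size_xy=1.5,
                          z_step=10.0, cells_per_cluster=100,
                          cluster_diameter_um=120.0,
                          dead_fraction=dead_fraction, seed=3)
        _, _, truth = generate_cluster_nuclei(cfg)
        n_dead = sum(n.is_dead for n in truth.nuclei)
        assert n_dead == round(dead_fraction * len(truth.nuclei))

    def test_two_cluster_separation_geometry(self):
        cfg = SceneConfig(image_shape=(5, 200, 560), pixel_size_xy=2.5,
                          z_step=25.0, cells_per_cluster=60, seed=9)
        centers = cfg.default_two_cluster_centers()
        _, _, truth = generate_cluster_nuclei(cfg, centers)
        pos = np.array([[n.z_um, n.y_um, n.x_um] for n in truth.nuclei])
        left = pos[pos[:, 2] < centers[0][2] + 150]
        right = pos[pos[:, 2] > centers[1][2] - 150]
        gap = min(np.linalg.norm(a - b) for a in left[:30] for b in right[:30])
        assert gap >= cfg.cluster_spacing_um - cfg.cluster_diameter_um

    def test_impossible_packing_raises(self):
        cfg = SceneConfig(image_shape=(5, 64, 64), pixel_size_xy=1.5,
                          cells_per_cluster=500, cluster_diameter_um=40.0,
                          seed=0)
        with pytest.raises(ValueError, match="cells_per_cluster"):
            generate_cluster_nuclei(cfg)


class TestBridgeScene:
    def test_reproducible_and_roi_clear_of_artefacts(self, bridge_config):
        a = generate_bridge_scene(bridge_config, render_viability=False)
        b = generate_bridge_scene(bridge_config, render_viability=False)
        np.testing.assert_array_equal(a.reflection.voxels, b.reflection.voxels)
        np.testing.assert_array_equal(a.factin.voxels, b.factin.voxels)
        roi = a.truth.roi_suggestion
        ys, xs = roi.slices()
        assert not a.truth.artefact_mask[ys, xs].any()
        assert not a.truth.cluster_mask[ys, xs].any()

    def test_density_multiplier_scales_roi_signal(self, bridge_config):
        cfg = replace(bridge_config, noise_gaussian_sd=0.0, background=0.0,
                      fiber_density=0.0)
        means = {}
        for mult in (1.0, 2.0):
            sc = generate_bridge_scene(cfg, bridge_density_multiplier=mult,
                                       bridge_fiber_density=3.0,
                                       roi_size_um=(300.0, 80.0),
                                       render_viability=False)
            means[mult] = intensity_density(
                sc.reflection, sc.truth.roi_suggestion,
                mask=sc.truth.artefact_mask).mean
        # drawing is linear in fiber count up to rare overlaps
        assert means[2.0] / means[1.0] == pytest.approx(2.0, rel=0.25)

    def test_treated_rods_aligned_control_uniform(self, bridge_config):
        treated = generate_bridge_scene(bridge_config, treated=True,
                                        factin_kappa=40.0,
                                        render_viability=False)
        control = generate_bridge_scene(bridge_config, treated=False,
                                        render_viability=False)
        t_angles = np.array(treated.truth.per_cell_orientation)
        c_angles = np.array(control.truth.per_cell_orientation)
        t_prop = np.mean(axial_distance(t_angles, 0.0) <= 10.0)
        c_prop = np.mean(axial_distance(c_angles, 0.0) <= 10.0)
        assert t_prop > 0.9
        # uniform axial: expected 2*10/180, allow 3 SE at this sample size
        p = 20.0 / 180.0
        se = np.sqrt(p * (1 - p) / len(c_angles))
        assert abs(c_prop - p) < 3 * se + 1e-9

    def test_corridor_too_narrow_for_roi(self, bridge_config):
        with pytest.raises(ValueError, match="corridor|ROI"):
            generate_bridge_scene(bridge_config, roi_size_um=(1000.0, 40.0),
                                  render_viability=False)

    def test_one_cluster_center_rejected(self, bridge_config):
        cfg = replace(bridge_config,
                      cluster_centers_um=[(25.0, 200.0, 600.0)])
        with pytest.raises(ValueError, match="two cluster"):
            generate_bridge_scene(cfg, render_viability=False)
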