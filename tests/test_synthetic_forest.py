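"""Simulator contracts: Poisson counts, determinism, true-volume
accounting, LiDAR return structure, and the inventory protocols."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from canopyscale.inventory_volume import NestedDesign, plot_volume
from canopyscale.pointcloud_ops import GROUND
from canopyscale.synthetic_forest import (
    InventoryConfig,
    LidarConfig,
    StandConfig,
    StandScene,
    Terrain,
    Tree,
    generate_stand,
    grid_mosaic,
    simulate_inventory,
    simulate_lidar,
    true_volume,
)

EXTENT = (0.0, 0.0, 100.0, 100.0)


def flat_config(density=0.05, terrain=None):
    return StandConfig(
        extent=EXTENT,
        units=grid_mosaic(EXTENT, 1, 1, densities=density),
        terrain=terrain or Terrain(base=100.0),
    )


def test_tree_invariants_enforced():
    with pytest.raises(ValueError):
        Tree(x=0, y=0, dbh=-1, height=10, crown_radius=1, crown_base=2)
    with pytest.raises(ValueError):
        Tree(x=0, y=0, dbh=20, height=1.0, crown_radius=1, crown_base=0.5)
    with pytest.raises(ValueError):
        Tree(x=0, y=0, dbh=20, height=20, crown_radius=1, crown_base=25)


def test_empty_stand_when_density_zero():
    scene = generate_stand(flat_config(density=0.0), seed=1)
    assert scene.n_trees == 0
    assert true_volume(scene, box(*EXTENT)) == 0.0


def test_poisson_tree_counts_over_seeds():
    counts = [generate_stand(flat_config(0.05), seed=s).n_trees for s in range(100)]
    counts = np.asarray(counts)
    # per-seed counts within 3*sqrt(500) of the mean 500; the mean of 100
    # seeds within 4 standard errors
    assert np.all(np.abs(counts - 500) < 3 * math.sqrt(500) + 1)
    assert abs(counts.mean() - 500) < 4 * math.sqrt(500 / 100)


def test_stand_determinism():
    cfg = flat_config(0.03)
    a = generate_stand(cfg, seed=42)
    b = generate_stand(cfg, seed=42)
    assert a.trees.equals(b.trees)
    c = generate_stand(cfg, seed=43)
    assert not a.trees.equals(c.trees)


def test_trees_inside_extent_with_valid_allometry():
    scene = generate_stand(flat_config(0.05), seed=2)
    t = scene.trees
    assert ((t.x >= 0) & (t.x <= 100) & (t.y >= 0) & (t.y <= 100)).all()
    assert (t.height > 1.3).all()
    assert ((t.crown_base >= 0) & (t.crown_base < t.height)).all()
    assert (t.crown_radius > 0).all()


def test_true_volume_single_tree_hand_value():
    import pandas as pd

    tree = pd.DataFrame(
        {
            "tree_id": [0], "x": [50.0], "y": [50.0], "dbh": [20.0], "height": [25.0],
            "crown_radius": [2.0], "crown_base": [5.0], "species_code": ["beech"], "unit_id": ["u"],
        }
    )
    scene = StandScene(tree, Terrain(), grid_mosaic(EXTENT, 1, 1, 0.0), EXTENT)
    v = true_volume(scene, box(*EXTENT), form_factor=0.5)
    assert v == pytest.approx((math.pi / 4) * 0.2**2 * 25 * 0.5, abs=1e-12)  # 0.3927
    assert true_volume(scene, box(0, 0, 10, 10)) == 0.0  # no stems in there


def test_true_volume_additive_over_partition():
    scene = generate_stand(flat_config(0.05), seed=9)
    whole = true_volume(scene, box(*EXTENT))
    left = true_volume(scene, box(0, 0, 50, 100))
    right = true_volume(scene, box(50, 0, 100, 100))
    assert left + right == pytest.approx(whole, rel=1e-9)


def test_degenerate_polygon_warns_and_returns_zero():
    scene = generate_stand(flat_config(0.02), seed=1)
    with pytest.warns(UserWarning):
        assert true_volume(scene, box(0, 0, 0, 0)) == 0.0


class TestLidar:
    def test_treeless_scene_all_ground(self):
        scene = generate_stand(flat_config(0.0), seed=1)
        cloud = simulate_lidar(scene, LidarConfig(seed=5, vertical_noise_sd=0.05))
        assert (cloud.classification == GROUND).all()
        resid = cloud.z - scene.terrain.elevation(cloud.x, cloud.y)
        assert np.abs(resid).max() < 0.05 * 5

    def test_max_vegetation_height_reaches_tree_top(self):
        import pandas as pd

        tree = pd.DataFrame(
            {
                "tree_id": [0], "x": [50.0], "y": [50.0], "dbh": [50.0], "height": [30.0],
                "crown_radius": [4.0], "crown_base": [10.0], "species_code": ["beech"], "unit_id": ["u"],
            }
        )
        scene = StandScene(tree, Terrain(base=0.0), grid_mosaic(EXTENT, 1, 1, 0.0), EXTENT)
        cloud = simulate_lidar(scene, LidarConfig(pulse_density=50, seed=3, vertical_noise_sd=0.02))
        veg = cloud.classification != GROUND
        assert veg.any()
        zmax = cloud.z[veg].max()
        assert zmax == pytest.approx(30.0, abs=0.5)
        assert zmax <= 30.0 + 5 * 0.02 + 1e-9

    def test_pulse_density_doubles_return_count(self):
        scene = generate_stand(flat_config(0.03), seed=4)
        n8 = [len(simulate_lidar(scene, LidarConfig(pulse_density=8, seed=s))) for s in range(5)]
        n16 = [len(simulate_lidar(scene, LidarConfig(pulse_density=16, seed=s))) for s in range(5)]
        ratio = np.mean(n16) / np.mean(n8)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_lidar_determinism(self):
        scene = generate_stand(flat_config(0.03), seed=4)
        a = simulate_lidar(scene, LidarConfig(seed=11))
        b = simulate_lidar(scene, LidarConfig(seed=11))
        assert np.array_equal(a.z, b.z) and np.array_equal(a.return_no, b.return_no)

    def test_return_numbers_start_at_one(self):
        scene = generate_stand(flat_config(0.05), seed=4)
        cloud = simulate_lidar(scene, LidarConfig(seed=1))
        assert cloud.return_no.min() == 1
        assert cloud.return_no.max() <= LidarConfig().max_returns_per_pulse


class TestInventory:
    def test_unknown_design_rejected(self):
        scene = generate_stand(flat_config(0.02), seed=1)
        with pytest.raises(ValueError):
            simulate_inventory(scene, [(50, 50)], "plots", InventoryConfig(), seed=0)

    def test_noise_free_census_matches_true_volume(self):
        scene = generate_stand(flat_config(0.05), seed=6)
        cfg = InventoryConfig(gps_sigma=0.0, dbh_measure_sd=0.0)
        rec = simulate_inventory(scene, [(50.0, 50.0)], "census_1ha", cfg, seed=0)[0]
        vol = plot_volume(rec["stems"], "census_1ha", cfg.form_factor)
        big = scene.trees[scene.trees.dbh > 7.0]
        truth = true_volume(
            StandScene(big, scene.terrain, scene.units, scene.extent), box(0, 0, 100, 100)
        )
        assert vol == pytest.approx(truth, rel=1e-9)
        assert rec["recorded_center"] == rec["true_center"]

    def test_census_excludes_dbh_exactly_7(self):
        import pandas as pd

        trees = pd.DataFrame(
            {
                "tree_id": [0, 1], "x": [40.0, 60.0], "y": [50.0, 50.0],
                "dbh": [7.0, 7.1], "height": [9.0, 9.0], "crown_radius": [1.0, 1.0],
                "crown_base": [2.0, 2.0], "species_code": ["beech"] * 2, "unit_id": ["u"] * 2,
            }
        )
        scene = StandScene(trees, Terrain(), grid_mosaic(EXTENT, 1, 1, 0.0), EXTENT)
        rec = simulate_inventory(
            scene, [(50.0, 50.0)], "census_1ha", InventoryConfig(0, 0), seed=0
        )[0]
        assert len(rec["stems"]) == 1  # DBH > 7 cm is strict
        assert rec["stems"].dbh_cm.iloc[0] == pytest.approx(7.1)

    def test_gps_error_moves_recorded_center_not_selection(self):
        scene = generate_stand(flat_config(0.05), seed=8)
        noisy = simulate_inventory(
            scene, [(50.0, 50.0)], "nested_0.05ha", InventoryConfig(gps_sigma=3.0, dbh_measure_sd=0.0), seed=5
        )[0]
        clean = simulate_inventory(
            scene, [(50.0, 50.0)], "nested_0.05ha", InventoryConfig(gps_sigma=0.0, dbh_measure_sd=0.0), seed=5
        )[0]
        # same stems selected (selection from the true centre)...
        assert np.array_equal(
            np.sort(noisy["stems"].dist_m.to_numpy()), np.sort(clean["stems"].dist_m.to_numpy())
        )
        # ...but the exported centre moved
        assert noisy["recorded_center"] != noisy["true_center"]

    def test_inventory_determinism(self):
        scene = generate_stand(flat_config(0.04), seed=8)
        cfg = InventoryConfig()
        a = simulate_inventory(scene, [(30, 30), (70, 70)], "nested_0.05ha", cfg, seed=2)
        b = simulate_inventory(scene, [(30, 30), (70, 70)], "nested_0.05ha", cfg, seed=2)
        assert a[0]["recorded_center"] == b[0]["recorded_center"]
        assert a[1]["stems"].equals(b[1]["stems"])


def test_nested_plot_volume_unbiased_noise_free(closure_results):
    """Noise-free closure: the nested expansion estimator's mean over 500
    plots lands within 5% of the realised stand volume density."""
    assert abs(closure_results["nested_rel_err"]) < 0.05


def test_edge_effect_simple_mch_regressions(ordering_results):
    """With 2 m GPS error, simple volume~MCH fits are better on 1 ha plots
    than on 0.05 ha plots on average — the plot edge-effect mechanism."""
    df = ordering_results
    assert df.r2_simple_1ha.mean() > df.r2_simple_005ha.mean()
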