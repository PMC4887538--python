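"""End-to-end simulation experiments on synthetic stands.

These functions wire the whole pipeline together — generate a stand,
fly synthetic LiDAR, normalise heights, clip plots, compute metrics,
estimate field volumes, fit models — and express the study's structural
questions as measurable quantities:

* :func:`plot_size_experiment` — does a model trained on 1 ha plots
  validate better than one trained on 0.05 ha plots when plot centres
  carry GPS error? (edge-effect / misregistration mechanism)
* :func:`aggregation_experiment` — do the two models agree better at
  management-unit level than cell-by-cell?
* :func:`inventory_closure_experiment` — does nested-plot expansion
  recover true stand volume density without measurement noise?
* :func:`stability_dataset` — paired (metric, volume) data with a chosen
  population R^2 for the sample-size permutation analysis.

Problem sizes default to desk scale (a 360 m scene, 25 one-hectare and
100 nested plots per scene) so a 20-scene replicate set runs in minutes;
LiDAR pulse density and the field protocols keep their survey defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .canopy_metrics import MetricConfig, metrics_table
from .inventory_volume import NestedDesign, plot_volume
from .landscape_scaling import CELL_SIZES, aggregate_units, compare_models, grid_predict
from .pointcloud_ops import GROUND, PlotPolygon, build_dtm, clip_plot, median_nodes_per_cell, normalize_heights
from .synthetic_forest import (
    InventoryConfig,
    LidarConfig,
    StandConfig,
    StandScene,
    Terrain,
    generate_stand,
    grid_mosaic,
    simulate_inventory,
    simulate_lidar,
    true_volume,
)
from .volume_modeling import evaluate, fit_stepwise, split_train_test

__all__ = [
    "EXPERIMENT_CANDIDATES",
    "make_scene",
    "normalized_cloud",
    "plot_dataset",
    "plot_size_experiment",
    "aggregation_experiment",
    "inventory_closure_experiment",
    "stability_dataset",
]

# predictor pool for the small-n experiment fits: the height and
# cover/density metrics classically retained in area-based volume models
EXPERIMENT_CANDIDATES = ["MCH", "CV", "var", "q20", "q40", "q70", "q90", "kurt", "cov", "dens"]


def make_scene(seed: int, side: float = 360.0, n_units_axis: int = 3) -> StandScene:
    """A management-mosaic beech scene: an n-by-n unit grid of even-aged
    stands over gently undulating terrain.

    Units differ in development stage: Weibull DBH scale 16-40 cm, with
    stem density coupled to stem size by a Reineke-type self-thinning
    rule (density ~ size^-1.6, ~300-450 stems/ha at 25 cm), so older
    units are taller and sparser — the structure of a managed even-aged
    mosaic.
    """
    rng = np.random.default_rng(seed)
    n = n_units_axis**2
    extent = (0.0, 0.0, side, side)
    scales = rng.uniform(16.0, 40.0, n)
    densities = rng.uniform(0.030, 0.045, n) * (scales / 25.0) ** -1.6
    units = grid_mosaic(
        extent,
        n_units_axis,
        n_units_axis,
        densities=densities,
        weibull_scales=scales,
    )
    cfg = StandConfig(
        extent=extent,
        units=units,
        terrain=Terrain(base=350.0, slope_x=0.02, slope_y=-0.01, amplitude=4.0, wavelength=150.0),
    )
    return generate_stand(cfg, seed=int(rng.integers(2**31)))


def normalized_cloud(scene: StandScene, lidar_cfg: LidarConfig):
    """Simulate the survey and normalise heights.

    The DTM is a TIN over per-1 m-cell median nodes of the
    ground-classified returns (the simulator labels classes; the
    progressive-TIN classifier is validated against those labels
    separately and is not re-run inside every replicate experiment).
    """
    cloud = simulate_lidar(scene, lidar_cfg)
    ground = cloud.subset(cloud.classification == GROUND)
    dtm = build_dtm(median_nodes_per_cell(ground, cell=1.0))
    return normalize_heights(cloud, dtm), dtm


def _plot_centers(rng, side, margin, spacing, jitter):
    """Jittered square grid of plot centres inside the margin."""
    lo, hi = margin, side - margin
    k = max(2, int(np.floor((hi - lo) / spacing)) + 1)
    g = np.linspace(lo, hi, k)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts = pts + rng.uniform(-jitter, jitter, pts.shape)
    return np.clip(pts, lo, hi)


def plot_dataset(
    scene: StandScene,
    cloud_norm,
    centers,
    scale: str,
    inv_cfg: InventoryConfig,
    seed: int,
    metric_cfg: MetricConfig = MetricConfig(),
):
    """Field volumes and LiDAR metrics for a set of plot centres.

    Field volume uses the true centre (the crew stands there); the LiDAR
    clip uses the recorded (GPS-shifted) centre — the misregistration
    mechanism under study. Returns (metrics DataFrame, volume Series).
    """
    if scale == "1ha":
        design_label, shape = "census_1ha", "square100"
        design = "census_1ha"
    elif scale == "0.05ha":
        design_label, shape = "nested_0.05ha", "circle25"
        design = NestedDesign()
    else:
        raise ValueError(f"unknown scale {scale!r}")
    inv = simulate_inventory(scene, centers, design_label, inv_cfg, seed=seed)
    vols = pd.Series(
        {rec["plot_id"]: plot_volume(rec["stems"], design, inv_cfg.form_factor) for rec in inv}
    )
    plots = [
        (rec["plot_id"], clip_plot(cloud_norm, PlotPolygon(rec["recorded_center"], shape)))
        for rec in inv
    ]
    mt = metrics_table(plots, metric_cfg)
    return mt, vols.reindex(mt.index)


def _fit_and_validate(mt, vols, scale, seed):
    train, test = split_train_test(list(mt.index), 0.7, seed=seed)
    model = fit_stepwise(
        mt.loc[train], vols.loc[train], EXPERIMENT_CANDIDATES, plot_scale=scale, seed=seed
    )
    r2, rmse = evaluate(model, mt, vols, ids=test)
    model.fit_stats = {"r2": r2, "rmse": rmse, "n_train": len(train), "n_test": len(test)}
    return model


def _simple_r2(x: np.ndarray, y: np.ndarray) -> float:
    sxx = ((x - x.mean()) ** 2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    return float(sxy**2 / (sxx * syy)) if sxx > 0 and syy > 0 else np.nan


def run_scene_models(seed: int, gps_sigma: float = 2.0, side: float = 360.0):
    """One replicate of the plot-size comparison: build a scene, derive
    both plot datasets, fit+validate both models.

    Returns a dict with the fitted models, the datasets, and summary
    numbers (held-out R^2/RMSE per scale and the simple volume~MCH R^2
    per scale on all plots).
    """
    ss = np.random.SeedSequence(seed)
    s_scene, s_lidar, s_inv1, s_inv2, s_split = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)]
    scene = make_scene(s_scene, side=side)
    cloud, _ = normalized_cloud(scene, LidarConfig(seed=s_lidar))
    inv_cfg = InventoryConfig(gps_sigma=gps_sigma)
    rng = np.random.default_rng(s_inv1)

    centers_1ha = _plot_centers(rng, side, margin=52.0, spacing=64.0, jitter=6.0)
    mt1, v1 = plot_dataset(scene, cloud, centers_1ha, "1ha", inv_cfg, seed=s_inv1)
    centers_005 = _plot_centers(rng, side, margin=16.0, spacing=33.0, jitter=8.0)
    mt0, v0 = plot_dataset(scene, cloud, centers_005, "0.05ha", inv_cfg, seed=s_inv2)

    model1 = _fit_and_validate(mt1, v1, "1ha", s_split)
    model0 = _fit_and_validate(mt0, v0, "0.05ha", s_split)
    out = {
        "scene": scene,
        "cloud": cloud,
        "model_1ha": model1,
        "model_005ha": model0,
        "data_1ha": (mt1, v1),
        "data_005ha": (mt0, v0),
        "r2_1ha": model1.fit_stats["r2"],
        "r2_005ha": model0.fit_stats["r2"],
        "rmse_1ha": model1.fit_stats["rmse"],
        "rmse_005ha": model0.fit_stats["rmse"],
        "r2_simple_1ha": _simple_r2(mt1["MCH"].to_numpy(float), v1.to_numpy(float)),
        "r2_simple_005ha": _simple_r2(mt0["MCH"].to_numpy(float), v0.to_numpy(float)),
    }
    return out


def plot_size_experiment(n_scenes: int = 20, seed: int = 0, gps_sigma: float = 2.0) -> pd.DataFrame:
    """Replicate :func:`run_scene_models` over independent scenes.

    Returns one row per scene with held-out and simple-regression R^2 for
    both plot scales; the headline comparison is the fraction of scenes
    where the 1 ha model validates better than the 0.05 ha model.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, sub in enumerate(ss.spawn(n_scenes)):
        res = run_scene_models(int(sub.generate_state(1)[0] % 2**31), gps_sigma=gps_sigma)
        rows.append(
            {
                "scene": i,
                "r2_1ha": res["r2_1ha"],
                "r2_005ha": res["r2_005ha"],
                "rmse_1ha": res["rmse_1ha"],
                "rmse_005ha": res["rmse_005ha"],
                "r2_simple_1ha": res["r2_simple_1ha"],
                "r2_simple_005ha": res["r2_simple_005ha"],
            }
        )
    return pd.DataFrame(rows)


def aggregation_experiment(seed: int = 0, side: float = 360.0):
    """Wall-to-wall maps from both models on one scene, aggregated to the
    management units.

    Returns a dict with unit-level R^2 between the two models' unit
    totals, the cell-level R^2 (each fine cell's 0.05 ha prediction vs
    the 1 ha prediction of the coarse cell containing it), the unit
    summary tables and the two maps.
    """
    res = run_scene_models(seed, side=side)
    scene, cloud = res["scene"], res["cloud"]
    extent = scene.extent
    map1 = grid_predict(cloud, res["model_1ha"], extent=extent)
    map0 = grid_predict(cloud, res["model_005ha"], extent=extent)

    units = [(u.unit_id, u.polygon) for u in scene.units]
    sum1 = aggregate_units(map1, units)
    sum0 = aggregate_units(map0, units)
    unit_r2, rmse_identity, table = compare_models(sum1, sum0)

    # pair each fine cell with the coarse cell containing its centre
    ratio = map1.cell_size / map0.cell_size
    ny0, nx0 = map0.shape
    fine_i, fine_j = np.meshgrid(np.arange(ny0), np.arange(nx0), indexing="ij")
    cx = map0.origin[0] + (fine_j + 0.5) * map0.cell_size
    cy = map0.origin[1] + (fine_i + 0.5) * map0.cell_size
    jj = np.clip(((cx - map1.origin[0]) / map1.cell_size).astype(int), 0, map1.shape[1] - 1)
    ii = np.clip(((cy - map1.origin[1]) / map1.cell_size).astype(int), 0, map1.shape[0] - 1)
    v_fine = map0.values[fine_i, fine_j].ravel()
    v_coarse = map1.values[ii, jj].ravel()
    ok = np.isfinite(v_fine) & np.isfinite(v_coarse)
    cell_r2 = _simple_r2(v_coarse[ok], v_fine[ok])

    return {
        "unit_r2": unit_r2,
        "cell_r2": cell_r2,
        "rmse_identity_m3": rmse_identity,
        "unit_table": table,
        "summaries_1ha": sum1,
        "summaries_005ha": sum0,
        "map_1ha": map1,
        "map_005ha": map0,
        "scene": scene,
    }


def inventory_closure_experiment(seed: int = 0, n_nested: int = 500, side: float = 300.0):
    """Noise-free inventory closure on a homogeneous stand.

    Nested 0.05 ha plots (random centres) and a tiling of census 1 ha
    plots are simulated with all error terms zero; their mean per-hectare
    volume is compared with the realised true volume density of the
    stand. Returns relative errors (fractions) and the raw numbers.
    """
    from shapely.geometry import box

    extent = (0.0, 0.0, side, side)
    units = grid_mosaic(extent, 1, 1, densities=0.05)
    cfg = StandConfig(extent=extent, units=units, terrain=Terrain())
    scene = generate_stand(cfg, seed=seed)
    noise_free = InventoryConfig(gps_sigma=0.0, dbh_measure_sd=0.0)

    area_ha = scene.area_ha()
    truth_all = true_volume(scene, box(*extent)) / area_ha
    big = scene.trees[scene.trees["dbh"] > 7.0]
    truth_census = (
        true_volume(
            StandScene(big, scene.terrain, scene.units, scene.extent), box(*extent)
        )
        / area_ha
    )

    rng = np.random.default_rng(seed + 1)
    centers = rng.uniform(13.0, side - 13.0, (n_nested, 2))
    inv = simulate_inventory(scene, centers, "nested_0.05ha", noise_free, seed=seed + 2)
    nested_mean = float(
        np.mean([plot_volume(rec["stems"], NestedDesign()) for rec in inv])
    )

    k = int(side // 100)
    tiles = [(50.0 + 100.0 * i, 50.0 + 100.0 * j) for i in range(k) for j in range(k)]
    inv_c = simulate_inventory(scene, tiles, "census_1ha", noise_free, seed=seed + 3)
    census_mean = float(np.mean([plot_volume(rec["stems"], "census_1ha") for rec in inv_c]))

    return {
        "true_density_m3_ha": truth_all,
        "true_density_census_m3_ha": truth_census,
        "nested_mean_m3_ha": nested_mean,
        "census_mean_m3_ha": census_mean,
        "nested_rel_err": nested_mean / truth_all - 1.0,
        "census_rel_err": census_mean / truth_census - 1.0,
        "n_nested": n_nested,
        "n_census": len(tiles),
    }


def stability_dataset(n: int = 1100, r2_pop: float = 0.68, seed: int = 0):
    """Paired (MCH, volume) samples whose population R^2 is r2_pop.

    MCH ~ N(18, 4^2) m; volume follows the bundled 0.05 ha reference
    slope (25.89 m^3 ha^-1 per metre of MCH) plus Gaussian noise sized to
    the target R^2 — a desk-scale stand-in for a large nested-plot
    network feeding the sample-size permutation analysis.
    """
    rng = np.random.default_rng(seed)
    slope = 25.89
    mch = rng.normal(18.0, 4.0, n)
    signal_sd = slope * 4.0
    noise_sd = signal_sd * np.sqrt((1.0 - r2_pop) / r2_pop)
    vol = -144.85 + slope * mch + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"MCH": mch, "volume_m3_ha": vol})
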