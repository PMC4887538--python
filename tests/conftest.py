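"""Shared fixtures: small synthetic scenes and the expensive replicate
experiments, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from canopyscale.experiments import (
    aggregation_experiment,
    inventory_closure_experiment,
    make_scene,
    plot_size_experiment,
)
from canopyscale.pointcloud_ops import PointCloud
from canopyscale.synthetic_forest import (
    LidarConfig,
    StandConfig,
    Terrain,
    generate_stand,
    grid_mosaic,
    simulate_lidar,
)


def make_cloud(h_norm, return_no=None):
    """A minimal normalised cloud with the given heights (for metric tests)."""
    h = np.asarray(h_norm, dtype=float)
    n = h.size
    return PointCloud(
        x=np.linspace(0.0, 1.0, n) if n else np.empty(0),
        y=np.zeros(n),
        z=h + 100.0,
        return_no=np.ones(n, dtype=np.int32) if return_no is None else np.asarray(return_no, np.int32),
        classification=np.full(n, 4, dtype=np.int8),
        h_norm=h,
    )


@pytest.fixture(scope="session")
def small_scene():
    """An 80 m homogeneous stand on undulating terrain with its simulated
    cloud — used by the ground-classification / DTM / normalisation tests."""
    extent = (0.0, 0.0, 80.0, 80.0)
    cfg = StandConfig(
        extent=extent,
        units=grid_mosaic(extent, 1, 1, densities=0.03),
        terrain=Terrain(base=400.0, slope_x=0.03, slope_y=0.01, amplitude=2.0, wavelength=60.0),
    )
    scene = generate_stand(cfg, seed=7)
    cloud = simulate_lidar(scene, LidarConfig(seed=8))
    return scene, cloud


@pytest.fixture(scope="session")
def ordering_results():
    """20 replicate scenes of the plot-size comparison with 2 m GPS error."""
    return plot_size_experiment(n_scenes=20, seed=0, gps_sigma=2.0)


@pytest.fixture(scope="session")
def aggregation_results():
    """Three synthetic landscapes: unit-level vs cell-level model agreement."""
    return [aggregation_experiment(seed=s) for s in (0, 1, 2)]


@pytest.fixture(scope="session")
def closure_results():
    return inventory_closure_experiment(seed=3, n_nested=500)
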