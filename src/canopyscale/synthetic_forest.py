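"""Synthetic forest stands, discrete-return LiDAR, and field inventories.

This module generates beech-like stands with fully known ground truth so
that every downstream stage of the area-based pipeline (ground
classification, height normalisation, canopy metrics, volume models,
landscape aggregation) can be tested without any external data.

The stand model is deliberately simple but structurally realistic:

* stems are placed by a homogeneous Poisson process within each
  management unit, at that unit's target density;
* DBH is drawn from a per-unit Weibull distribution (the standard
  diameter-distribution model for even-aged stands);
* total height follows a saturating Chapman-Richards-like allometry
  ``h = h_max * (1 - exp(-k * dbh)) ** c``;
* crown radius and crown-base height are linear in DBH;
* terrain is a smooth undulating surface (tilted plane + sinusoid).

The LiDAR simulator drops vertical pulses on a Poisson pattern, intersects
them with ellipsoidal crowns, and emits discrete returns with a per-metre
canopy interception probability, so pulse density, occlusion and ground
visibility behave like a leaf-on discrete-return survey.

The inventory simulator reproduces the field protocol: a full census of
stems above a DBH threshold on 1 ha squares, or the nested
concentric-circle design on 0.05 ha plots, with GPS error applied to the
*exported* plot centre (field crews measure from the true physical point;
the misregistration only affects where the LiDAR clip lands).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, box, mapping

from .pointcloud_ops import GROUND, VEGETATION, PointCloud

__all__ = [
    "Tree",
    "Terrain",
    "UnitSpec",
    "StandConfig",
    "StandScene",
    "LidarConfig",
    "InventoryConfig",
    "grid_mosaic",
    "generate_stand",
    "true_volume",
    "simulate_lidar",
    "simulate_inventory",
    "stem_records_frame",
]

TREE_COLUMNS = [
    "tree_id",
    "x",
    "y",
    "dbh",
    "height",
    "crown_radius",
    "crown_base",
    "species_code",
    "unit_id",
]


@dataclass(frozen=True)
class Tree:
    """A single stem; coordinates in metres, DBH in centimetres."""

    x: float
    y: float
    dbh: float
    height: float
    crown_radius: float
    crown_base: float
    species_code: str = "beech"

    def __post_init__(self) -> None:
        if self.dbh <= 0:
            raise ValueError("dbh must be > 0")
        if self.height <= 1.3:
            raise ValueError("height must exceed breast height (1.3 m)")
        if not (0 <= self.crown_base < self.height):
            raise ValueError("crown_base must lie in [0, height)")
        if self.crown_radius <= 0:
            raise ValueError("crown_radius must be > 0")


@dataclass(frozen=True)
class Terrain:
    """Smooth analytic ground surface: tilted plane plus a sinusoidal swell."""

    base: float = 350.0
    slope_x: float = 0.0
    slope_y: float = 0.0
    amplitude: float = 0.0
    wavelength: float = 120.0

    def elevation(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = self.base + self.slope_x * x + self.slope_y * y
        if self.amplitude:
            w = 2.0 * math.pi / self.wavelength
            z = z + self.amplitude * np.sin(w * x) * np.cos(w * y)
        return z


@dataclass(frozen=True)
class UnitSpec:
    """One management unit: a polygon plus its stand-structure parameters.

    density is stems per square metre; dbh follows Weibull(shape, scale cm).
    """

    polygon: Polygon
    unit_id: str
    density: float
    weibull_shape: float = 2.2
    weibull_scale: float = 28.0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")


@dataclass(frozen=True)
class StandConfig:
    """Parameters for :func:`generate_stand`.

    Height allometry defaults put a 40 cm DBH beech at ~30 m; crown
    allometries give a 40 cm tree a 2.5 m crown radius.
    """

    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    units: tuple[UnitSpec, ...]
    h_max: float = 35.0
    h_k: float = 0.0528
    h_c: float = 1.2
    crown_radius_intercept: float = 0.5
    crown_radius_slope: float = 0.05  # m per cm DBH
    crown_base_intercept: float = 1.0
    crown_base_slope: float = 0.25  # m per cm DBH
    min_dbh: float = 1.0
    terrain: Terrain = field(default_factory=Terrain)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must have positive area")
        if not self.units:
            raise ValueError("at least one management unit is required")


@dataclass
class StandScene:
    """Ground-truth scene: stems, terrain, management-unit mosaic, extent."""

    trees: pd.DataFrame  # TREE_COLUMNS
    terrain: Terrain
    units: tuple[UnitSpec, ...]
    extent: tuple[float, float, float, float]
    seed: int | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def area_ha(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return (xmax - xmin) * (ymax - ymin) / 10_000.0

    def save_stems_csv(self, path) -> None:
        self.trees.rename(
            columns={
                "dbh": "dbh_cm",
                "height": "height_m",
                "crown_radius": "crown_radius_m",
                "crown_base": "crown_base_m",
            }
        ).to_csv(path, index=False)

    def save_units_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"unit_id": u.unit_id, "density": u.density},
                "geometry": mapping(u.polygon),
            }
            for u in self.units
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


@dataclass(frozen=True)
class LidarConfig:
    """Discrete-return survey parameters (leaf-on defaults, ~16 pulses/m2)."""

    pulse_density: float = 16.0
    max_returns_per_pulse: int = 4
    vertical_noise_sd: float = 0.1
    canopy_interception_prob: float = 0.3  # per metre of crown traversed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pulse_density <= 0:
            raise ValueError("pulse_density must be > 0")
        if self.max_returns_per_pulse < 1:
            raise ValueError("max_returns_per_pulse must be >= 1")
        if self.vertical_noise_sd < 0:
            raise ValueError("vertical_noise_sd must be >= 0")
        if self.canopy_interception_prob < 0:
            raise ValueError("canopy_interception_prob must be >= 0")


@dataclass(frozen=True)
class InventoryConfig:
    """Field-measurement error model and stem-form parameter."""

    gps_sigma: float = 2.0
    dbh_measure_sd: float = 0.3
    form_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.gps_sigma < 0 or self.dbh_measure_sd < 0:
            raise ValueError("error standard deviations must be >= 0")
        if not (0 < self.form_factor <= 1):
            raise ValueError("form_factor must be in (0, 1]")


def grid_mosaic(
    extent: tuple[float, float, float, float],
    nx: int,
    ny: int,
    densities,
    weibull_scales=None,
    weibull_shapes=None,
) -> tuple[UnitSpec, ...]:
    """Tile the extent into an nx-by-ny mosaic of rectangular units.

    ``densities`` (and optionally per-unit Weibull scale/shape) are given
    row-major; scalars broadcast.
    """
    xmin, ymin, xmax, ymax = extent
    n = nx * ny
    densities = np.broadcast_to(np.asarray(densities, dtype=float), (n,))
    scales = np.broadcast_to(
        np.asarray(28.0 if weibull_scales is None else weibull_scales, dtype=float), (n,)
    )
    shapes = np.broadcast_to(
        np.asarray(2.2 if weibull_shapes is None else weibull_shapes, dtype=float), (n,)
    )
    dx = (xmax - xmin) / nx
    dy = (ymax - ymin) / ny
    units = []
    k = 0
    for j in range(ny):
        for i in range(nx):
            poly = box(xmin + i * dx, ymin + j * dy, xmin + (i + 1) * dx, ymin + (j + 1) * dy)
            units.append(
                UnitSpec(
                    polygon=poly,
                    unit_id=f"u{k:02d}",
                    density=float(densities[k]),
                    weibull_shape=float(shapes[k]),
                    weibull_scale=float(scales[k]),
                )
            )
            k += 1
    return tuple(units)


def _height_from_dbh(cfg: StandConfig, dbh: np.ndarray) -> np.ndarray:
    return cfg.h_max * (1.0 - np.exp(-cfg.h_k * dbh)) ** cfg.h_c


def generate_stand(config: StandConfig, seed: int) -> StandScene:
    """Generate a stand: Poisson stem placement per unit, Weibull DBH,
    deterministic allometries. Bit-identical output for identical
    (config, seed).
    """
    rng = np.random.default_rng(seed)
    frames = []
    tree_id0 = 0
    for unit in config.units:
        poly = unit.polygon
        uxmin, uymin, uxmax, uymax = poly.bounds
        area = poly.area
        if area <= 0:
            raise ValueError(f"unit {unit.unit_id} has zero area")
        n_expect = unit.density * (uxmax - uxmin) * (uymax - uymin)
        n = rng.poisson(n_expect)
        x = rng.uniform(uxmin, uxmax, n)
        y = rng.uniform(uymin, uymax, n)
        # rejection to the actual polygon keeps the process homogeneous at
        # the unit's density for non-rectangular units
        if not math.isclose(area, (uxmax - uxmin) * (uymax - uymin), rel_tol=1e-9):
            from shapely import contains_xy

            keep = contains_xy(poly, x, y)
            x, y = x[keep], y[keep]
            n = x.size
        dbh = _draw_dbh(rng, unit, n, config)
        height = _height_from_dbh(config, dbh)
        # redraw any stem whose allometric height is not above breast height
        bad = height <= 1.3
        for _ in range(100):
            if not bad.any():
                break
            dbh[bad] = _draw_dbh(rng, unit, int(bad.sum()), config)
            height = _height_from_dbh(config, dbh)
            bad = height <= 1.3
        if bad.any():
            raise RuntimeError(
                "height allometry kept producing trees at or below 1.3 m; "
                "check h_max/h_k/h_c against the DBH distribution"
            )
        crown_radius = config.crown_radius_intercept + config.crown_radius_slope * dbh
        crown_base = np.minimum(
            config.crown_base_intercept + config.crown_base_slope * dbh, 0.9 * height
        )
        frames.append(
            pd.DataFrame(
                {
                    "tree_id": np.arange(tree_id0, tree_id0 + n),
                    "x": x,
                    "y": y,
                    "dbh": dbh,
                    "height": height,
                    "crown_radius": crown_radius,
                    "crown_base": crown_base,
                    "species_code": "beech",
                    "unit_id": unit.unit_id,
                }
            )
        )
        tree_id0 += n
    trees = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TREE_COLUMNS)
    )
    return StandScene(
        trees=trees, terrain=config.terrain, units=config.units, extent=config.extent, seed=seed
    )


def _draw_dbh(rng, unit: UnitSpec, n: int, config: StandConfig) -> np.ndarray:
    dbh = unit.weibull_scale * rng.weibull(unit.weibull_shape, n)
    return np.maximum(dbh, config.min_dbh)


def stem_volume_array(dbh_cm, height_m, form_factor: float) -> np.ndarray:
    """Vectorised stem volume (m^3): cylinder on DBH and height times a form
    factor that folds in stem taper."""
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    return (math.pi / 4.0) * (dbh_cm / 100.0) ** 2 * height_m * form_factor


def true_volume(scene: StandScene, polygon: Polygon, form_factor: float = 0.5) -> float:
    """Total stem wood volume (m^3) of trees whose stem falls inside the
    polygon — stem-localised accounting: a tree on the boundary counts in
    full, its overhanging crown does not move volume across the line.
    """
    if not (0 < form_factor <= 1):
        raise ValueError("form_factor must be in (0, 1]")
    if polygon.area == 0:
        import warnings

        warnings.warn("degenerate polygon (area 0); returning 0 volume", stacklevel=2)
        return 0.0
    if scene.n_trees == 0:
        return 0.0
    from shapely import contains_xy

    x = scene.trees["x"].to_numpy()
    y = scene.trees["y"].to_numpy()
    # closed-boundary convention: stems exactly on the line belong to the plot
    inside = contains_xy(polygon, x, y) | contains_xy(polygon.boundary.buffer(1e-9), x, y)
    v = stem_volume_array(
        scene.trees["dbh"].to_numpy()[inside],
        scene.trees["height"].to_numpy()[inside],
        form_factor,
    )
    return float(v.sum())


def simulate_lidar(scene: StandScene, cfg: LidarConfig) -> PointCloud:
    """Simulate a discrete-return cloud over the scene.

    Pulses are a Poisson pattern at cfg.pulse_density; each descends
    vertically. For every crown ellipsoid it pierces, a vegetation return
    is emitted at the entry (upper) intersection with probability
    ``(1 - exp(-k * chord)) * exp(-k * canopy_above)`` where k is the
    per-metre interception probability — i.e. interception within this
    crown, attenuated by canopy already traversed. A ground return is
    emitted with the residual transmission ``exp(-k * total_chord)`` when
    the return budget allows. Gaussian vertical noise is added to all
    returns. Deterministic given cfg.seed.
    """
    xmin, ymin, xmax, ymax = scene.extent
    area = (xmax - xmin) * (ymax - ymin)
    if area <= 0:
        raise ValueError("scene extent has zero area")
    rng = np.random.default_rng(cfg.seed)
    n_pulse = rng.poisson(cfg.pulse_density * area)
    px = rng.uniform(xmin, xmax, n_pulse)
    py = rng.uniform(ymin, ymax, n_pulse)

    k_int = cfg.canopy_interception_prob
    if scene.n_trees and k_int > 0:
        tx = scene.trees["x"].to_numpy()
        ty = scene.trees["y"].to_numpy()
        tr = scene.trees["crown_radius"].to_numpy()
        th = scene.trees["height"].to_numpy()
        tb = scene.trees["crown_base"].to_numpy()
        pulse_idx, tree_idx = _crown_hits(px, py, tx, ty, tr)
    else:
        pulse_idx = tree_idx = np.empty(0, dtype=np.intp)

    if pulse_idx.size:
        d2 = (px[pulse_idx] - tx[tree_idx]) ** 2 + (py[pulse_idx] - ty[tree_idx]) ** 2
        frac = 1.0 - d2 / tr[tree_idx] ** 2  # (1 - (d/r)^2) of the ellipse section
        ok = frac > 0
        pulse_idx, tree_idx, frac = pulse_idx[ok], tree_idx[ok], frac[ok]
        semi = 0.5 * (th[tree_idx] - tb[tree_idx])
        zc = 0.5 * (th[tree_idx] + tb[tree_idx])
        half_chord = semi * np.sqrt(frac)
        z_top = zc + half_chord  # height above local ground at the tree base
        chord = 2.0 * half_chord

        # order hits within each pulse from canopy top downwards
        order = np.lexsort((-z_top, pulse_idx))
        pulse_idx = pulse_idx[order]
        tree_idx = tree_idx[order]
        z_top = z_top[order]
        chord = chord[order]

        tau = k_int * chord
        cum_tau = np.cumsum(tau)
        starts = np.r_[0, np.flatnonzero(np.diff(pulse_idx)) + 1]
        group_of = np.repeat(np.arange(starts.size), np.diff(np.r_[starts, pulse_idx.size]))
        cum_before = cum_tau - tau - np.where(starts[group_of] > 0, cum_tau[starts[group_of] - 1], 0.0)
        p_emit = (1.0 - np.exp(-tau)) * np.exp(-cum_before)
        emitted = rng.random(pulse_idx.size) < p_emit

        # return numbers: rank of emitted hits within pulse, capped
        emit_cum = np.cumsum(emitted)
        base = np.where(starts[group_of] > 0, emit_cum[starts[group_of] - 1], 0)
        rank = emit_cum - base  # 1-based rank among emitted, valid where emitted
        keep = emitted & (rank <= cfg.max_returns_per_pulse)

        veg_pulse = pulse_idx[keep]
        veg_retno = rank[keep].astype(np.int32)
        veg_z_local = z_top[keep]
        # total optical depth per pulse for the ground-return draw
        last = np.r_[starts[1:] - 1, pulse_idx.size - 1]
        tau_tot_hit = cum_tau[last] - np.where(starts > 0, cum_tau[starts - 1], 0.0)
        tau_total = np.zeros(n_pulse)
        tau_total[pulse_idx[starts]] = tau_tot_hit
        n_emitted = np.zeros(n_pulse, dtype=np.int64)
        counts = np.minimum(emit_cum[last] - np.where(starts > 0, emit_cum[starts - 1], 0),
                            cfg.max_returns_per_pulse)
        n_emitted[pulse_idx[starts]] = counts
    else:
        veg_pulse = np.empty(0, dtype=np.intp)
        veg_retno = np.empty(0, dtype=np.int32)
        veg_z_local = np.empty(0)
        tau_total = np.zeros(n_pulse)
        n_emitted = np.zeros(n_pulse, dtype=np.int64)

    ground_ok = (n_emitted < cfg.max_returns_per_pulse) & (
        rng.random(n_pulse) < np.exp(-tau_total)
    )
    gnd_pulse = np.flatnonzero(ground_ok)
    gnd_retno = (n_emitted[gnd_pulse] + 1).astype(np.int32)

    ground_z = scene.terrain.elevation(px, py)
    all_x = np.r_[px[veg_pulse], px[gnd_pulse]]
    all_y = np.r_[py[veg_pulse], py[gnd_pulse]]
    all_z = np.r_[ground_z[veg_pulse] + veg_z_local, ground_z[gnd_pulse]]
    if cfg.vertical_noise_sd > 0:
        all_z = all_z + rng.normal(0.0, cfg.vertical_noise_sd, all_z.size)
    all_retno = np.r_[veg_retno, gnd_retno]
    classification = np.r_[
        np.full(veg_pulse.size, VEGETATION, dtype=np.int8),
        np.full(gnd_pulse.size, GROUND, dtype=np.int8),
    ]
    order = np.lexsort((all_retno, np.r_[veg_pulse, gnd_pulse]))
    return PointCloud(
        x=all_x[order],
        y=all_y[order],
        z=all_z[order],
        return_no=all_retno[order],
        classification=classification[order],
    )


def _crown_hits(px, py, tx, ty, tr):
    """(pulse_idx, tree_idx) pairs with pulse inside a crown's bounding radius."""
    if tx.size == 0 or px.size == 0:
        e = np.empty(0, dtype=np.intp)
        return e, e
    rmax = float(tr.max())
    tree_kd = cKDTree(np.column_stack([tx, ty]))
    pulse_kd = cKDTree(np.column_stack([px, py]))
    hits = tree_kd.query_ball_tree(pulse_kd, rmax)
    tree_idx = np.repeat(np.arange(tx.size), [len(h) for h in hits])
    pulse_idx = np.concatenate([np.asarray(h, dtype=np.intp) for h in hits]) if len(hits) else np.empty(0, dtype=np.intp)
    if pulse_idx.size == 0:
        e = np.empty(0, dtype=np.intp)
        return e, e
    d2 = (px[pulse_idx] - tx[tree_idx]) ** 2 + (py[pulse_idx] - ty[tree_idx]) ** 2
    keep = d2 < tr[tree_idx] ** 2
    return pulse_idx[keep], tree_idx[keep]


def simulate_inventory(
    scene: StandScene,
    plot_centers,
    design: str,
    cfg: InventoryConfig,
    seed: int,
) -> list[dict]:
    """Simulate a field campaign over the given plot centres.

    design is ``"census_1ha"`` (100 m square, all stems with DBH > 7 cm) or
    ``"nested_0.05ha"`` (all stems within 12.5 m; the nested DBH rules are
    applied downstream at expansion time).

    Stem selection uses the TRUE plot centre — the crew stands at the
    physical point — while the *recorded* centre carries the GPS offset and
    is what a LiDAR clip would use. Measured DBH carries Gaussian error,
    truncated positive. Returns one record dict per plot with keys
    ``plot_id, true_center, recorded_center, stems`` (DataFrame with
    dist_m, dx, dy, dbh_cm, true_dbh_cm, height_m, species).
    """
    if design not in ("census_1ha", "nested_0.05ha"):
        raise ValueError(f"unknown design {design!r}")
    rng = np.random.default_rng(seed)
    x = scene.trees["x"].to_numpy()
    y = scene.trees["y"].to_numpy()
    dbh = scene.trees["dbh"].to_numpy()
    height = scene.trees["height"].to_numpy()
    out = []
    for i, (cx, cy) in enumerate(plot_centers):
        gx, gy = rng.normal(0.0, cfg.gps_sigma, 2) if cfg.gps_sigma > 0 else (0.0, 0.0)
        recorded = (cx + gx, cy + gy)
        if design == "census_1ha":
            sel = (np.abs(x - cx) <= 50.0) & (np.abs(y - cy) <= 50.0) & (dbh > 7.0)
        else:
            sel = (x - cx) ** 2 + (y - cy) ** 2 <= 12.5**2
        dx, dy = x[sel] - cx, y[sel] - cy
        meas = dbh[sel]
        if cfg.dbh_measure_sd > 0 and meas.size:
            meas = np.maximum(meas + rng.normal(0.0, cfg.dbh_measure_sd, meas.size), 0.1)
        stems = pd.DataFrame(
            {
                "dist_m": np.hypot(dx, dy),
                "dx": dx,
                "dy": dy,
                "dbh_cm": meas,
                "true_dbh_cm": dbh[sel],
                "height_m": height[sel],
                "species": scene.trees["species_code"].to_numpy()[sel],
            }
        )
        out.append(
            {
                "plot_id": f"p{i:04d}",
                "true_center": (float(cx), float(cy)),
                "recorded_center": (float(recorded[0]), float(recorded[1])),
                "design": design,
                "stems": stems,
            }
        )
    return out


def stem_records_frame(inventories: list[dict]) -> pd.DataFrame:
    """Flatten simulate_inventory output to one long stems table (the CSV
    exchange format: plot_id, dist_m, dbh_cm, height_m, species)."""
    rows = []
    for rec in inventories:
        df = rec["stems"].copy()
        df.insert(0, "plot_id", rec["plot_id"])
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["plot_id", "dist_m", "dbh_cm", "height_m", "species"])
    return pd.concat(rows, ignore_index=True)
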