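"""Wall-to-wall extrapolation of a plot-scale volume model and
aggregation to management units.

The normalised cloud is tiled with square cells at the model's plot
resolution: 100 m cells for a 1 ha model, sqrt(500) ~ 22.36 m cells for a
0.05 ha model (circles cannot tile, so equal-area squares are used). Each
cell's metric vector feeds the linear model; cells without any returns
are nodata, cells with returns but no vegetation returns predict 0 (bare
ground carries no canopy signal and no volume).

Unit aggregation intersects cells with unit polygons, area-weighting
partial cells, so totals are mass-consistent: unit totals plus the
outside-units remainder equal the whole-map total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .canopy_metrics import MetricConfig, compute_metrics
from .pointcloud_ops import PointCloud
from .volume_modeling import VolumeModel, predict

__all__ = [
    "VolumeMap",
    "CELL_SIZES",
    "grid_predict",
    "aggregate_units",
    "compare_models",
]

CELL_SIZES = {"1ha": 100.0, "0.05ha": math.sqrt(500.0)}


@dataclass
class VolumeMap:
    """Raster of predicted volume (m^3 ha^-1); NaN = nodata."""

    values: np.ndarray  # (ny, nx), row 0 southmost
    origin: tuple[float, float]  # lower-left corner of cell (0, 0)
    cell_size: float

    @property
    def shape(self):
        return self.values.shape

    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    def total_volume(self) -> float:
        """Whole-map total in m^3 (nodata cells contribute nothing)."""
        return float(np.nansum(self.values) * self.cell_area_ha())

    def cell_box(self, i: int, j: int):
        x0 = self.origin[0] + j * self.cell_size
        y0 = self.origin[1] + i * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def to_ascii_grid(self, path) -> None:
        ny, nx = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\nnrows {ny}\n")
            fh.write(f"xllcorner {self.origin[0]}\nyllcorner {self.origin[1]}\n")
            fh.write(f"cellsize {self.cell_size}\nnodata_value -9999\n")
            out = np.where(np.isfinite(self.values), self.values, -9999.0)
            np.savetxt(fh, out[::-1], fmt="%.2f")


def grid_predict(
    cloud: PointCloud,
    model: VolumeModel,
    cfg: MetricConfig = MetricConfig(),
    extent=None,
    cell_size: float | None = None,
) -> VolumeMap:
    """Tile the extent (default: cloud bounding box) with square cells at
    the model's plot scale, compute the metric vector per cell, and apply
    the model. Empty cells are nodata; negative predictions floor at 0."""
    if not cloud.is_normalized:
        raise ValueError("cloud must be normalised")
    if cell_size is None:
        if model.plot_scale not in CELL_SIZES:
            raise ValueError(
                f"model.plot_scale {model.plot_scale!r} has no default cell size; "
                "pass cell_size explicitly"
            )
        cell_size = CELL_SIZES[model.plot_scale]
    if extent is None:
        extent = (cloud.x.min(), cloud.y.min(), cloud.x.max(), cloud.y.max())
    xmin, ymin, xmax, ymax = extent
    nx = max(1, math.ceil((xmax - xmin) / cell_size - 1e-9))
    ny = max(1, math.ceil((ymax - ymin) / cell_size - 1e-9))
    jj = np.clip(np.floor((cloud.x - xmin) / cell_size).astype(np.int64), 0, nx - 1)
    ii = np.clip(np.floor((cloud.y - ymin) / cell_size).astype(np.int64), 0, ny - 1)
    inside = (cloud.x >= xmin) & (cloud.x <= xmax) & (cloud.y >= ymin) & (cloud.y <= ymax)

    values = np.full((ny, nx), np.nan)
    cell_id = ii * nx + jj
    for cid in np.unique(cell_id[inside]):
        mask = inside & (cell_id == cid)
        vec = compute_metrics(cloud.subset(mask), cfg)
        i, j = divmod(int(cid), nx)
        if any(not np.isfinite(vec[t]) for t in model.coefficients):
            # returns present but no vegetation returns: bare cell -> 0
            values[i, j] = 0.0
        else:
            values[i, j] = predict(model, vec, clip_negative=True)
    return VolumeMap(values=values, origin=(float(xmin), float(ymin)), cell_size=float(cell_size))


def aggregate_units(vmap: VolumeMap, units) -> pd.DataFrame:
    """Per-unit totals: sum over intersecting cells of cell volume-density
    times the intersected area (partial cells area-weighted).

    ``units`` is a list of (unit_id, shapely polygon) or objects with
    .unit_id/.polygon. Returns a DataFrame (unit_id, area_ha,
    total_m3_<...>, mean per ha) with one row per unit; a unit outside the
    map gets total 0 and outside_map=True.
    """
    norm = []
    for u in units:
        if isinstance(u, tuple):
            norm.append(u)
        else:
            norm.append((u.unit_id, u.polygon))
    ny, nx = vmap.shape
    rows = []
    for uid, poly in norm:
        uxmin, uymin, uxmax, uymax = poly.bounds
        j0 = max(0, int(math.floor((uxmin - vmap.origin[0]) / vmap.cell_size)))
        j1 = min(nx - 1, int(math.floor((uxmax - vmap.origin[0]) / vmap.cell_size)))
        i0 = max(0, int(math.floor((uymin - vmap.origin[1]) / vmap.cell_size)))
        i1 = min(ny - 1, int(math.floor((uymax - vmap.origin[1]) / vmap.cell_size)))
        total = 0.0
        covered_ha = 0.0
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                v = vmap.values[i, j]
                if not np.isfinite(v):
                    continue
                inter = poly.intersection(vmap.cell_box(i, j)).area
                if inter > 0:
                    total += v * inter / 10_000.0
                    covered_ha += inter / 10_000.0
        area_ha = poly.area / 10_000.0
        rows.append(
            {
                "unit_id": uid,
                "area_ha": area_ha,
                "total_m3": total,
                "mean_m3_ha": total / covered_ha if covered_ha > 0 else np.nan,
                "outside_map": covered_ha == 0.0,
            }
        )
    return pd.DataFrame(rows)


def compare_models(summaries_a: pd.DataFrame, summaries_b: pd.DataFrame):
    """Agreement between two models' per-unit totals.

    Returns (r2, rmse_identity, table): R^2 of the OLS regression of b on
    a; RMSE measured about the identity line (difference-between-models
    semantics); and the merged scatter table, which also carries the
    regression-line RMSE for reference.
    """
    a = summaries_a.set_index("unit_id")["total_m3"]
    b = summaries_b.set_index("unit_id")["total_m3"]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common units")
    x = a.loc[common].to_numpy(float)
    y = b.loc[common].to_numpy(float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    r2 = sxy**2 / (sxx * syy) if sxx > 0 and syy > 0 else np.nan
    rmse_identity = float(np.sqrt(np.mean((y - x) ** 2)))
    slope = sxy / sxx if sxx > 0 else np.nan
    intercept = y.mean() - slope * x.mean()
    rmse_regression = float(np.sqrt(np.mean((y - (intercept + slope * x)) ** 2)))
    table = pd.DataFrame(
        {"unit_id": common, "total_a_m3": x, "total_b_m3": y}
    ).reset_index(drop=True)
    table.attrs["rmse_regression"] = rmse_regression
    return float(r2), rmse_identity, table
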