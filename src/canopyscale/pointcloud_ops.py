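"""Point-cloud handling: ground classification, TIN DTM, height
normalisation and plot clipping.

All coordinates are planar, projected, metre units (UTM-style); no
reprojection is performed. Classification codes follow the LAS convention:
2 = ground, anything else vegetation/unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.spatial import Delaunay, QhullError

GROUND = 2
VEGETATION = 4
UNCLASSIFIED = 0

__all__ = [
    "GROUND",
    "VEGETATION",
    "UNCLASSIFIED",
    "PointCloud",
    "DTM",
    "PlotPolygon",
    "classify_ground",
    "build_dtm",
    "normalize_heights",
    "clip_plot",
]


@dataclass
class PointCloud:
    """Columnar discrete-return cloud.

    h_norm is height above the DTM and is NaN until
    :func:`normalize_heights` has been applied.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_no: np.ndarray
    classification: np.ndarray
    h_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.x.size
        for name in ("y", "z", "return_no", "classification"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name} length mismatch")
        if n and self.return_no.min() < 1:
            raise ValueError("return_no must be >= 1")

    def __len__(self) -> int:
        return self.x.size

    @property
    def is_normalized(self) -> bool:
        return self.h_norm is not None

    def subset(self, mask) -> "PointCloud":
        return PointCloud(
            x=self.x[mask],
            y=self.y[mask],
            z=self.z[mask],
            return_no=self.return_no[mask],
            classification=self.classification[mask],
            h_norm=None if self.h_norm is None else self.h_norm[mask],
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "z": self.z,
                "return_no": self.return_no,
                "class": self.classification,
            }
        )
        if self.h_norm is not None:
            df["h_norm"] = self.h_norm
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PointCloud":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            z=df["z"].to_numpy(float),
            return_no=df["return_no"].to_numpy(np.int32),
            classification=df["class"].to_numpy(np.int8),
            h_norm=df["h_norm"].to_numpy(float) if "h_norm" in df else None,
        )


@dataclass
class DTM:
    """1 m ground-elevation grid; NaN marks cells outside the TIN hull."""

    origin: tuple[float, float]  # (x, y) of the lower-left cell *center*
    elevation: np.ndarray  # shape (ny, nx), row 0 = southmost
    cell_size: float = 1.0

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.elevation.shape
        xs = self.origin[0] + self.cell_size * np.arange(nx)
        ys = self.origin[1] + self.cell_size * np.arange(ny)
        return xs, ys

    def sample(self, x, y) -> np.ndarray:
        """Bilinear ground elevation at arbitrary points; NaN outside."""
        xs, ys = self.cell_centers()
        interp = RegularGridInterpolator(
            (ys, xs), self.elevation, method="linear", bounds_error=False, fill_value=np.nan
        )
        return interp(np.column_stack([np.asarray(y, float).ravel(), np.asarray(x, float).ravel()]))

    def to_ascii_grid(self, path) -> None:
        ny, nx = self.elevation.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\nnrows {ny}\n")
            fh.write(f"xllcenter {self.origin[0]}\nyllcenter {self.origin[1]}\n")
            fh.write(f"cellsize {self.cell_size}\nnodata_value -9999\n")
            out = np.where(np.isfinite(self.elevation), self.elevation, -9999.0)
            np.savetxt(fh, out[::-1], fmt="%.3f")


@dataclass(frozen=True)
class PlotPolygon:
    """Field-plot footprint: 25 m diameter circle or 100 m square, centred
    on the (recorded) plot centre."""

    center: tuple[float, float]
    shape: str  # "circle25" | "square100"

    RADIUS = 12.5
    SIDE = 100.0

    def __post_init__(self) -> None:
        if self.shape not in ("circle25", "square100"):
            raise ValueError(f"unknown plot shape {self.shape!r}")

    def contains(self, x, y) -> np.ndarray:
        cx, cy = self.center
        if self.shape == "circle25":
            return (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2 <= self.RADIUS**2
        h = self.SIDE / 2.0
        return (np.abs(np.asarray(x) - cx) <= h) & (np.abs(np.asarray(y) - cy) <= h)

    def area_ha(self) -> float:
        if self.shape == "circle25":
            return math.pi * self.RADIUS**2 / 10_000.0
        return 1.0

    def to_shapely(self):
        from shapely.geometry import Point, box

        cx, cy = self.center
        if self.shape == "circle25":
            return Point(cx, cy).buffer(self.RADIUS, quad_segs=64)
        h = self.SIDE / 2.0
        return box(cx - h, cy - h, cx + h, cy + h)


def classify_ground(
    cloud: PointCloud,
    cell: float = 2.0,
    z_tol: float = 0.3,
    iterations: int = 3,
    max_slope: float = 0.5,
) -> PointCloud:
    """Progressive-TIN ground classification.

    Seeds with the lowest return per ``cell`` metre grid cell; seeds
    standing more than ``max_slope``-permitted relief above their 5x5-cell
    neighbourhood minimum are discarded (they are canopy over fully
    occluded cells). The ground set is then densified over ``iterations``
    passes that accept every return within ``z_tol`` of a TIN through the
    per-cell medians of the current ground set (median nodes suppress
    sensor noise; returns outside the node hull fall back to the nearest
    node). Purely z-shift invariant.
    """
    from scipy.interpolate import NearestNDInterpolator
    from scipy.ndimage import grey_erosion

    n = len(cloud)
    if n == 0:
        raise ValueError("empty cloud")
    if n < 3:
        out = cloud.subset(np.ones(n, bool))
        out.classification = np.full(n, GROUND, dtype=np.int8)
        return out

    x0, y0 = cloud.x.min(), cloud.y.min()
    ix = np.floor((cloud.x - x0) / cell).astype(np.int64)
    iy = np.floor((cloud.y - y0) / cell).astype(np.int64)
    nx, ny = int(ix.max()) + 1, int(iy.max()) + 1
    cell_id = ix * ny + iy
    order = np.lexsort((cloud.z, cell_id))
    first = np.r_[True, np.diff(cell_id[order]) != 0]
    seed_idx = order[first]

    # neighbourhood cleaning: a seed must not sit far above the lowest
    # seed within 2 cells — rejects canopy lowest-points in occluded cells
    zgrid = np.full((nx, ny), np.inf)
    zgrid[ix[seed_idx], iy[seed_idx]] = cloud.z[seed_idx]
    nb_min = grey_erosion(zgrid, size=(5, 5), mode="nearest")
    relief = max_slope * 2.0 * cell + 3.0 * z_tol
    ok = cloud.z[seed_idx] <= nb_min[ix[seed_idx], iy[seed_idx]] + relief
    seeds = seed_idx[ok]
    ground = np.zeros(n, dtype=bool)
    ground[seeds] = True

    for _ in range(iterations):
        gid = cell_id[ground]
        uniq, inv = np.unique(gid, return_inverse=True)
        node_x = _groupby_median(cloud.x[ground], inv, uniq.size)
        node_y = _groupby_median(cloud.y[ground], inv, uniq.size)
        node_z = _groupby_median(cloud.z[ground], inv, uniq.size)
        if uniq.size < 3:
            break
        try:
            tri = Delaunay(np.column_stack([node_x, node_y]))
        except QhullError:
            break
        zs = LinearNDInterpolator(tri, node_z)(cloud.x, cloud.y)
        miss = ~np.isfinite(zs)
        if miss.any():
            near = NearestNDInterpolator(np.column_stack([node_x, node_y]), node_z)
            zs[miss] = near(cloud.x[miss], cloud.y[miss])
        new_ground = np.abs(cloud.z - zs) <= z_tol
        new_ground[seeds] = True
        if (new_ground == ground).all():
            break
        ground = new_ground

    out = cloud.subset(np.ones(n, bool))
    out.classification = np.where(ground, GROUND, VEGETATION).astype(np.int8)
    return out


def _groupby_median(values: np.ndarray, inv: np.ndarray, n_groups: int) -> np.ndarray:
    order = np.argsort(inv, kind="stable")
    sorted_vals = values[order]
    counts = np.bincount(inv, minlength=n_groups)
    out = np.empty(n_groups)
    start = 0
    for g in range(n_groups):
        c = counts[g]
        seg = sorted_vals[start : start + c]
        out[g] = np.median(seg) if c else np.nan
        start += c
    return out


def thin_lowest_per_cell(cloud: PointCloud, cell: float = 1.0) -> PointCloud:
    """Keep only the lowest return per grid cell (standard DTM pre-thinning)."""
    n = len(cloud)
    if n == 0:
        return cloud
    ix = np.floor((cloud.x - cloud.x.min()) / cell).astype(np.int64)
    iy = np.floor((cloud.y - cloud.y.min()) / cell).astype(np.int64)
    cell_id = ix * (iy.max() + 1) + iy
    order = np.lexsort((cloud.z, cell_id))
    first = np.r_[True, np.diff(cell_id[order]) != 0]
    mask = np.zeros(n, dtype=bool)
    mask[order[first]] = True
    return cloud.subset(mask)


def median_nodes_per_cell(cloud: PointCloud, cell: float = 1.0) -> PointCloud:
    """One synthetic node per grid cell at the per-cell median (x, y, z) of
    the returns — an unbiased, noise-suppressing thinning for DTM input
    (the lowest-return rule is biased low by the noise minimum)."""
    n = len(cloud)
    if n == 0:
        return cloud
    ix = np.floor((cloud.x - cloud.x.min()) / cell).astype(np.int64)
    iy = np.floor((cloud.y - cloud.y.min()) / cell).astype(np.int64)
    cell_id = ix * (iy.max() + 1) + iy
    uniq, inv = np.unique(cell_id, return_inverse=True)
    return PointCloud(
        x=_groupby_median(cloud.x, inv, uniq.size),
        y=_groupby_median(cloud.y, inv, uniq.size),
        z=_groupby_median(cloud.z, inv, uniq.size),
        return_no=np.ones(uniq.size, dtype=np.int32),
        classification=np.full(uniq.size, GROUND, dtype=np.int8),
    )


def build_dtm(ground: PointCloud, cell_size: float = 1.0) -> DTM:
    """Delaunay-TIN linear interpolation of ground returns at cell centres.

    Cells outside the convex hull of the ground points are NaN (nodata).
    """
    gx, gy, gz = ground.x, ground.y, ground.z
    if gx.size < 3:
        raise ValueError("need at least 3 ground points for a TIN")
    try:
        tri = Delaunay(np.column_stack([gx, gy]))
    except QhullError as exc:
        raise ValueError("ground points are collinear; cannot triangulate") from exc
    interp = LinearNDInterpolator(tri, gz)
    x0 = math.floor(gx.min()) + cell_size / 2.0
    y0 = math.floor(gy.min()) + cell_size / 2.0
    nx = max(1, math.ceil((gx.max() - x0) / cell_size) + 1)
    ny = max(1, math.ceil((gy.max() - y0) / cell_size) + 1)
    xs = x0 + cell_size * np.arange(nx)
    ys = y0 + cell_size * np.arange(ny)
    xx, yy = np.meshgrid(xs, ys)
    zz = interp(xx.ravel(), yy.ravel()).reshape(ny, nx)
    return DTM(origin=(x0, y0), elevation=zz, cell_size=cell_size)


def normalize_heights(cloud: PointCloud, dtm: DTM) -> PointCloud:
    """h_norm = z - bilinear DTM elevation; points over nodata are dropped
    (their count is available as len(in) - len(out))."""
    ground_z = dtm.sample(cloud.x, cloud.y)
    ok = np.isfinite(ground_z)
    out = cloud.subset(ok)
    out.h_norm = cloud.z[ok] - ground_z[ok]
    return out


def clip_plot(cloud: PointCloud, plot: PlotPolygon) -> PointCloud:
    """Subset of returns inside the plot footprint (closed boundary:
    points exactly on the edge belong to the plot). Preserves all fields;
    an empty result is valid."""
    return cloud.subset(plot.contains(cloud.x, cloud.y))
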