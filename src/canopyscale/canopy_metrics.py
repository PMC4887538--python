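"""Canopy structural metrics from a clipped, normalised point cloud.

The suite mirrors the standard area-based toolbox (FUSION-style
cloudmetrics): return counts, height distribution moments, L-moments,
percentiles, canopy relief ratio, quadratic/cubic mean heights, cover and
density fractions, and 2 m height strata counts up to 40 m.

Conventions (fixed so tests can be exact):

* vegetation returns are those with h_norm >= height_threshold (0.5 m);
* variance uses the n-1 denominator; skewness and kurtosis are the
  biased standardised 3rd/4th sample moments (kurtosis is *not* excess);
* percentiles interpolate linearly between order statistics at rank
  p*(n-1)+1 (the common "type 7" rule);
* L-moments use the unbiased order-statistic (b-weight) estimators;
* the mode is the midpoint of the fullest 0.5 m histogram bin (ties go
  to the lowest bin);
* cover = first vegetation returns / all first returns (percent);
  density = vegetation returns / all returns (percent);
* strata s2..s40 count vegetation returns in [0,2), [2,4), ... [38,40);
  returns above 40 m stay in every other metric but not in the strata;
* degenerate plots (no vegetation returns) yield NaN markers, never
  exceptions, so wall-to-wall gridding can proceed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pointcloud_ops import PointCloud

__all__ = ["MetricConfig", "compute_metrics", "metrics_table", "METRIC_COLUMNS", "PERCENTILES"]

PERCENTILES = [1, 5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 99]

_STRATA = list(range(2, 41, 2))

METRIC_COLUMNS = (
    ["totRET"]
    + [f"ret{k}" for k in range(1, 10)]
    + ["minCH", "maxCH", "MCH", "medCH", "modCH"]
    + ["stdev", "var", "CV", "intD", "skew", "kurt", "AAD", "MADmed", "MADmod"]
    + ["L1", "L2", "L3", "L4", "Lskew", "Lkurt"]
    + [f"q{p}" for p in PERCENTILES]
    + ["CRR", "CQM", "CCM", "cov", "dens"]
    + [f"s{s}" for s in _STRATA]
)


@dataclass(frozen=True)
class MetricConfig:
    height_threshold: float = 0.5  # m; vegetation-return cutoff
    strata_width: float = 2.0
    strata_max: float = 40.0
    mode_bin: float = 0.5
    cover_reference: str = "first-returns"  # or "all-returns"

    def __post_init__(self) -> None:
        if self.height_threshold < 0:
            raise ValueError("height_threshold must be >= 0")
        if self.strata_width <= 0:
            raise ValueError("strata_width must be > 0")


def _lmoments(h: np.ndarray) -> tuple[float, float, float, float]:
    """Unbiased sample L-moments l1..l4 via probability-weighted moments."""
    n = h.size
    x = np.sort(h)
    i = np.arange(1, n + 1, dtype=float)
    b0 = x.mean()
    b1 = np.sum((i - 1) * x) / (n * (n - 1)) if n >= 2 else np.nan
    b2 = np.sum((i - 1) * (i - 2) * x) / (n * (n - 1) * (n - 2)) if n >= 3 else np.nan
    b3 = (
        np.sum((i - 1) * (i - 2) * (i - 3) * x) / (n * (n - 1) * (n - 2) * (n - 3))
        if n >= 4
        else np.nan
    )
    l1 = b0
    l2 = 2 * b1 - b0
    l3 = 6 * b2 - 6 * b1 + b0
    l4 = 20 * b3 - 30 * b2 + 12 * b1 - b0
    return l1, l2, l3, l4


def _binned_mode(h: np.ndarray, width: float) -> float:
    """Midpoint of the fullest histogram bin of width `width` anchored at 0;
    ties resolve to the lowest bin."""
    idx = np.floor(h / width).astype(np.int64)
    uniq, counts = np.unique(idx, return_counts=True)
    best = uniq[np.argmax(counts)]  # np.unique sorts, argmax takes first max
    return (best + 0.5) * width


def compute_metrics(cloud: PointCloud, cfg: MetricConfig = MetricConfig()) -> pd.Series:
    """The full metric vector for one plot or grid cell as a pandas Series
    in METRIC_COLUMNS order."""
    if not cloud.is_normalized:
        raise ValueError("cloud must be normalised before computing metrics")
    out = pd.Series(np.nan, index=METRIC_COLUMNS, dtype=float)

    tot = len(cloud)
    out["totRET"] = tot
    for k in range(1, 10):
        out[f"ret{k}"] = int(np.sum(cloud.return_no == k))

    h_all = cloud.h_norm
    veg = h_all >= cfg.height_threshold
    h = h_all[veg]
    n = h.size

    for s in _STRATA:
        out[f"s{s}"] = 0.0
    if n:
        below = h[h < cfg.strata_max]
        idx = np.floor(below / cfg.strata_width).astype(np.int64)
        for j, s in enumerate(_STRATA):
            out[f"s{s}"] = float(np.sum(idx == j))

    out["dens"] = 100.0 * n / tot if tot else 0.0
    if cfg.cover_reference == "first-returns":
        first_all = int(np.sum(cloud.return_no == 1))
        first_veg = int(np.sum(cloud.return_no[veg] == 1))
        out["cov"] = 100.0 * first_veg / first_all if first_all else 0.0
    else:
        out["cov"] = out["dens"]

    if n == 0:
        return out

    mean = float(h.mean())
    hmin = float(h.min())
    hmax = float(h.max())
    med = float(np.median(h))
    mode = _binned_mode(h, cfg.mode_bin)
    out["minCH"], out["maxCH"], out["MCH"], out["medCH"], out["modCH"] = hmin, hmax, mean, med, mode
    qs = np.percentile(h, PERCENTILES)  # linear interpolation = "type 7"
    for p, q in zip(PERCENTILES, qs):
        out[f"q{p}"] = q
    out["CRR"] = (mean - hmin) / (hmax - hmin) if hmax > hmin else 0.0
    out["CQM"] = float(np.sqrt(np.mean(h**2)))
    out["CCM"] = float(np.cbrt(np.mean(h**3)))
    out["L1"] = mean

    if n >= 2:
        out["AAD"] = float(np.mean(np.abs(h - mean)))
        out["MADmed"] = float(np.median(np.abs(h - med)))
        out["MADmod"] = float(np.median(np.abs(h - mode)))
        var = float(h.var(ddof=1))
        sd = float(np.sqrt(var))
        out["var"] = var
        out["stdev"] = sd
        out["CV"] = sd / mean if mean != 0 else np.nan
        out["intD"] = out["q75"] - out["q25"]
        m2 = float(h.var(ddof=0))
        if m2 > 0:
            m3 = float(np.mean((h - mean) ** 3))
            m4 = float(np.mean((h - mean) ** 4))
            out["skew"] = m3 / m2**1.5
            out["kurt"] = m4 / m2**2
        else:
            out["skew"] = 0.0
            out["kurt"] = 0.0
        l1, l2, l3, l4 = _lmoments(h)
        out["L2"] = l2
        if n >= 3:
            out["L3"] = l3
            out["Lskew"] = l3 / l2 if l2 != 0 else np.nan
        if n >= 4:
            out["L4"] = l4
            out["Lkurt"] = l4 / l2 if l2 != 0 else np.nan
    return out


def metrics_table(
    plots: list[tuple[str, PointCloud]], cfg: MetricConfig = MetricConfig()
) -> pd.DataFrame:
    """One metric row per plot, indexed and ordered by plot_id as given."""
    ids = [pid for pid, _ in plots]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate plot_id")
    rows = {pid: compute_metrics(cloud, cfg) for pid, cloud in plots}
    df = pd.DataFrame(rows).T.reindex(columns=METRIC_COLUMNS)
    df.index.name = "plot_id"
    return df
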