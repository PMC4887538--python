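"""Permutation experiment: how inventory sample size affects the
stability of the wood-volume ~ LiDAR-metric regression.

For each sample size x, draw x plots without replacement, fit a simple
OLS regression of volume on one LiDAR metric (MCH by default), and record
R^2 and RMSE; repeat ``reps`` times per size. The regressions are fully
vectorised (closed-form simple OLS over a matrix of resampled rows), so
tens of thousands of fits run in seconds.

``summarize_stability`` turns the box-plot picture into a number: the
smallest sample size from which the interquartile range of R^2 stays at
or below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PermutationDesign", "PermutationResult", "run_permutations", "summarize_stability"]


@dataclass(frozen=True)
class PermutationDesign:
    sizes: tuple[int, ...]
    reps: int = 1000
    predictor: str = "MCH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if any(x < 3 for x in self.sizes):
            raise ValueError("every sample size must be >= 3")

    @property
    def n_regressions(self) -> int:
        return len(self.sizes) * self.reps


@dataclass
class PermutationResult:
    design: PermutationDesign
    r2: dict[int, np.ndarray]  # size -> (reps,)
    rmse: dict[int, np.ndarray]
    n_regressions: int
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long format: size, rep, r2, rmse."""
        parts = [
            pd.DataFrame(
                {
                    "size": x,
                    "rep": np.arange(self.design.reps),
                    "r2": self.r2[x],
                    "rmse": self.rmse[x],
                }
            )
            for x in self.design.sizes
        ]
        return pd.concat(parts, ignore_index=True)


def _simple_ols_rows(xs: np.ndarray, ys: np.ndarray):
    """Row-wise simple OLS: xs, ys are (reps, x). Returns (r2, rmse)."""
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    sxx = ((xs - xm) ** 2).sum(axis=1)
    sxy = ((xs - xm) * (ys - ym)).sum(axis=1)
    syy = ((ys - ym) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        rss = syy - slope * sxy
        r2 = np.where(syy > 0, 1.0 - rss / syy, np.nan)
    rmse = np.sqrt(np.maximum(rss, 0.0) / xs.shape[1])
    return r2, rmse


def run_permutations(
    volumes, metric_values, design: PermutationDesign
) -> PermutationResult:
    """Run the full permutation grid.

    volumes and metric_values are paired arrays/Series over the available
    plots; every size in design.sizes must be <= their length. Subsets
    whose predictor values are constant are redrawn (and counted).
    """
    y_all = np.asarray(volumes, dtype=float)
    x_all = np.asarray(metric_values, dtype=float)
    if y_all.shape != x_all.shape or y_all.ndim != 1:
        raise ValueError("volumes and metric_values must be equal-length 1-D arrays")
    n = y_all.size
    if max(design.sizes) > n:
        raise ValueError("sample size exceeds number of available plots")
    ss = np.random.SeedSequence(design.seed)
    child = ss.spawn(len(design.sizes))
    r2_out: dict[int, np.ndarray] = {}
    rmse_out: dict[int, np.ndarray] = {}
    n_regressions = 0
    n_redrawn = 0
    for x, sub in zip(design.sizes, child):
        rng = np.random.default_rng(sub)
        # without-replacement draw per rep: take the first x of a random
        # permutation of all n plots (argsort of iid uniforms)
        idx = np.argsort(rng.random((design.reps, n)), axis=1)[:, :x]
        xs = x_all[idx]
        ys = y_all[idx]
        for _ in range(100):
            degenerate = np.flatnonzero(np.ptp(xs, axis=1) == 0)
            if degenerate.size == 0:
                break
            n_redrawn += degenerate.size
            redo = np.argsort(rng.random((degenerate.size, n)), axis=1)[:, :x]
            xs[degenerate] = x_all[redo]
            ys[degenerate] = y_all[redo]
        r2, rmse = _simple_ols_rows(xs, ys)
        n_regressions += design.reps
        r2_out[x] = r2
        rmse_out[x] = rmse
    return PermutationResult(
        design=design,
        r2=r2_out,
        rmse=rmse_out,
        n_regressions=n_regressions,
        n_redrawn=n_redrawn,
    )


def summarize_stability(result: PermutationResult, tolerance: float = 0.05):
    """Per-size five-number summaries of R^2 and RMSE, plus the stability
    threshold: the smallest size x such that IQR(R^2) <= tolerance for x
    and every larger size (NaN if never reached).

    Returns (summary DataFrame, threshold).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    rows = []
    for x in result.design.sizes:
        for name, arr in (("r2", result.r2[x]), ("rmse", result.rmse[x])):
            q1, med, q3 = np.nanpercentile(arr, [25, 50, 75])
            rows.append(
                {
                    "size": x,
                    "stat": name,
                    "min": float(np.nanmin(arr)),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(np.nanmax(arr)),
                    "iqr": float(q3 - q1),
                }
            )
    summary = pd.DataFrame(rows)
    sizes = sorted(result.design.sizes)
    iqr_by_size = {
        x: summary.loc[(summary["size"] == x) & (summary["stat"] == "r2"), "iqr"].iloc[0]
        for x in sizes
    }
    threshold = np.nan
    for k, x in enumerate(sizes):
        if all(iqr_by_size[s] <= tolerance for s in sizes[k:]):
            threshold = x
            break
    return summary, threshold
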