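"""Plot wood volume ~ LiDAR metrics: train/test split, stepwise-AIC
multiple linear regression, validation, and prediction.

The stepwise search is bidirectional from the intercept-only model: at
each step the single add-or-drop move with the largest AIC decrease is
taken; the search stops when no move decreases AIC. AIC is
``n * ln(RSS/n) + 2 * (p + 1)`` with p predictors (additive constants
cancel in comparisons). Fits are ordinary least squares.

Two published reference equations for temperate beech forest are bundled
(:data:`REFERENCE_MODEL_1HA`, :data:`REFERENCE_MODEL_005HA`) so
predictions can be made and checked without refitting:

    volume(1 ha)    = 120.32 - 1.74 var - 4.38 q20 + 16.64 q40
                      + 9.7 q70 - 11.05 kurt
    volume(0.05 ha) = -144.85 + 25.89 MCH + 67.64 CV
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VolumeModel",
    "REFERENCE_MODEL_1HA",
    "REFERENCE_MODEL_005HA",
    "DEFAULT_CANDIDATES",
    "split_train_test",
    "fit_stepwise",
    "evaluate",
    "predict",
]

# metric columns usable as regression candidates: everything except raw
# acquisition-dependent counts (total/per-return counts and strata)
from .canopy_metrics import METRIC_COLUMNS

DEFAULT_CANDIDATES = [
    c
    for c in METRIC_COLUMNS
    if not (c == "totRET" or c.startswith("ret") or (c[0] == "s" and c[1:].isdigit()))
]


@dataclass
class VolumeModel:
    """A linear wood-volume predictor on named canopy metrics."""

    intercept: float
    coefficients: dict[str, float]
    plot_scale: str = ""  # "1ha" | "0.05ha"
    training_plot_ids: tuple = ()
    fit_stats: dict = field(default_factory=dict)  # r2 / rmse on held-out data
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coefficients": self.coefficients,
                    "plot_scale": self.plot_scale,
                    "training_plot_ids": list(self.training_plot_ids),
                    "fit_stats": self.fit_stats,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "VolumeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            plot_scale=d.get("plot_scale", ""),
            training_plot_ids=tuple(d.get("training_plot_ids", ())),
            fit_stats=d.get("fit_stats", {}),
            seed=d.get("seed"),
        )


REFERENCE_MODEL_1HA = VolumeModel(
    intercept=120.32,
    coefficients={"var": -1.74, "q20": -4.38, "q40": 16.64, "q70": 9.7, "kurt": -11.05},
    plot_scale="1ha",
)

REFERENCE_MODEL_005HA = VolumeModel(
    intercept=-144.85,
    coefficients={"MCH": 25.89, "CV": 67.64},
    plot_scale="0.05ha",
)


def split_train_test(plot_ids, train_fraction: float = 0.7, seed: int = 0):
    """Random disjoint, exhaustive split with |train| = round(f*n);
    deterministic given seed."""
    ids = list(plot_ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 plots to split")
    n_train = int(np.floor(train_fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with intercept column prepended; returns (beta, rss, rank)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid), rank


def _aic(n: int, rss: float, p: int, rss_floor: float = 1e-300) -> float:
    # floor RSS at numerical-noise scale so a perfect fit does not make
    # AIC unboundedly favour piling on further terms
    return n * np.log(max(rss, rss_floor) / n) + 2.0 * (p + 1)


def fit_stepwise(
    metrics_table: pd.DataFrame,
    volumes: pd.Series,
    candidate_metrics=None,
    plot_scale: str = "",
    seed: int | None = None,
    max_steps: int = 200,
) -> VolumeModel:
    """Bidirectional stepwise-AIC OLS of volume on canopy metrics.

    Rows with missing values in any candidate are dropped. Candidates that
    are constant or would make the design rank-deficient are never entered.
    """
    if candidate_metrics is None:
        candidate_metrics = [c for c in DEFAULT_CANDIDATES if c in metrics_table.columns]
    df = metrics_table.loc[:, list(candidate_metrics)].copy()
    df["_y"] = volumes.reindex(df.index)
    df = df.dropna()
    y = df["_y"].to_numpy(float)
    n = len(df)
    if n <= 2:
        raise ValueError("too few complete rows to fit")
    # drop constant candidates up front
    candidates = [c for c in candidate_metrics if df[c].nunique() > 1]

    selected: list[str] = []
    _, rss, _ = _ols(np.empty((n, 0)), y)
    rss_floor = n * (1e-9 * (np.abs(y).max() + 1.0)) ** 2
    current_aic = _aic(n, rss, 0, rss_floor)

    for _ in range(max_steps):
        best = (None, None, current_aic)  # (action, term, aic)
        for term in candidates:
            if term in selected:
                continue
            trial = selected + [term]
            if n <= len(trial) + 1:
                continue
            X = df[trial].to_numpy(float)
            beta, rss, rank = _ols(X, y)
            if rank < len(trial) + 1:
                continue  # collinear with already-selected terms
            a = _aic(n, rss, len(trial), rss_floor)
            if a < best[2] - 1e-10:
                best = ("add", term, a)
        for term in selected:
            trial = [t for t in selected if t != term]
            X = df[trial].to_numpy(float)
            _, rss, _ = _ols(X, y)
            a = _aic(n, rss, len(trial), rss_floor)
            if a < best[2] - 1e-10:
                best = ("drop", term, a)
        if best[0] is None:
            break
        if best[0] == "add":
            selected.append(best[1])
        else:
            selected.remove(best[1])
        current_aic = best[2]

    beta, rss, _ = _ols(df[selected].to_numpy(float), y)
    return VolumeModel(
        intercept=float(beta[0]),
        coefficients={t: float(b) for t, b in zip(selected, beta[1:])},
        plot_scale=plot_scale,
        training_plot_ids=tuple(df.index),
        seed=seed,
    )


def predict(model: VolumeModel, metrics, clip_negative: bool = True):
    """Evaluate the linear model on one MetricVector (Series/dict) or a
    metrics table (DataFrame). Negative predictions are floored at 0 by
    default (volume cannot be negative); pass clip_negative=False for the
    raw value."""
    is_frame = isinstance(metrics, pd.DataFrame)
    get = (lambda t: metrics[t]) if is_frame or isinstance(metrics, pd.Series) else (
        lambda t: metrics[t]
    )
    val = model.intercept
    for term, coef in model.coefficients.items():
        try:
            x = get(term)
        except KeyError:
            raise KeyError(f"metric {term!r} required by the model is missing") from None
        val = val + coef * x
    if is_frame:
        val = np.asarray(val, dtype=float)
        return np.maximum(val, 0.0) if clip_negative else val
    val = float(val)
    return max(val, 0.0) if clip_negative else val


def evaluate(model: VolumeModel, metrics_table: pd.DataFrame, volumes: pd.Series, ids=None):
    """(R^2, RMSE) of model predictions against observed volumes on the
    given plot ids (default: all rows). R^2 = 1 - RSS/TSS about the
    observed mean; NaN when the observed volumes have zero variance."""
    if ids is not None:
        ids = list(ids)
        if not ids:
            raise ValueError("ids is empty")
        metrics_table = metrics_table.loc[ids]
        volumes = volumes.loc[ids]
    obs = volumes.to_numpy(float)
    pred = np.asarray(predict(model, metrics_table, clip_negative=False), dtype=float)
    resid = obs - pred
    rss = float(resid @ resid)
    tss = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    rmse = float(np.sqrt(np.mean(resid**2)))
    return r2, rmse
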