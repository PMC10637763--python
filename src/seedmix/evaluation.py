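"""Metrics for composition regression and mix-level aggregation.

Four metrics are reported, matching common practice for proportion-regression
benchmarks:

* MAE — mean absolute error over all (image, category) pairs, the primary
  metric (fractions, so 0.037 means 3.7 percentage points of mass on average);
* MSE — mean squared error over the same pairs, penalizing large errors;
* R² — pooled coefficient of determination, 1 − SS_res/SS_tot, with the
  baseline predictor being the per-category mean of the evaluated truth;
* max MAE/seed — the largest per-category MAE, naming the worst-predicted
  variety.

Mix-level predictions are the arithmetic mean of the per-image predicted
compositions of one mix; averaging simplex vectors stays on the simplex, so
no renormalization is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import VarietyCatalog
from .losses import sparsemax
from .manifest import KEY_COLUMNS, MixManifest, PredictionBatch

__all__ = [
    "MetricsReport",
    "UndefinedMetricError",
    "mae",
    "mse",
    "r2_score",
    "per_seed_mae",
    "aggregate_by_mix",
    "metrics_report",
    "simulate_noisy_predictions",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. R^2 with constant truth)."""


def _align(pred: PredictionBatch, truth: MixManifest | pd.DataFrame, level: str):
    """Return (pred_matrix, truth_matrix) aligned on keys; error on orphans."""
    wcols = pred.weight_columns
    if level == "image":
        tdf = truth.rows if isinstance(truth, MixManifest) else truth
        keys = list(KEY_COLUMNS)
    else:
        tdf = truth.mix_truth() if isinstance(truth, MixManifest) else truth
        keys = ["mix_id"]
    pdf = pred.rows
    merged = pdf.merge(tdf, on=keys, how="outer", suffixes=("_pred", "_true"),
                       indicator=True)
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        raise KeyError(
            f"{len(orphans)} rows present on only one side of the match: "
            f"{orphans[keys].to_dict('records')[:5]}"
        )
    p = merged[[f"{c}_pred" for c in wcols]].to_numpy(dtype=float)
    t = merged[[f"{c}_true" for c in wcols]].to_numpy(dtype=float)
    return p, t


def mae(pred: PredictionBatch, truth, level: str = "image") -> float:
    """Mean of |predicted − true| over all (row, category) pairs."""
    p, t = _align(pred, truth, level)
    return float(np.abs(p - t).mean())


def mse(pred: PredictionBatch, truth, level: str = "image") -> float:
    """Mean of (predicted − true)² over all (row, category) pairs."""
    p, t = _align(pred, truth, level)
    return float(((p - t) ** 2).mean())


def r2_score(pred: PredictionBatch, truth, level: str = "image") -> float:
    """Pooled 1 − SS_res/SS_tot against the per-category-mean baseline.

    The baseline is the per-category mean of the *evaluated* truth, so a
    predictor that always outputs those means scores exactly 0.  Raises
    :class:`UndefinedMetricError` when the truth is constant (SS_tot = 0).
    """
    p, t = _align(pred, truth, level)
    if t.shape[0] < 2:
        raise UndefinedMetricError("R^2 needs at least 2 rows")
    ss_res = float(((p - t) ** 2).sum())
    ss_tot = float(((t - t.mean(axis=0, keepdims=True)) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: constant truth (SS_tot = 0)")
    return 1.0 - ss_res / ss_tot


def per_seed_mae(
    pred: PredictionBatch, truth, catalog: VarietyCatalog | None = None,
    level: str = "image",
) -> tuple[dict[str, float], tuple[str, float]]:
    """Per-category MAE map and the (label, value) of its maximum.

    Ties on the maximum are broken by catalog order.
    """
    cat = catalog or pred.catalog
    p, t = _align(pred, truth, level)
    per = np.abs(p - t).mean(axis=0)
    mapping = {n: float(v) for n, v in zip(cat.names, per)}
    best = int(np.argmax(per))  # argmax returns the first (catalog-order) tie
    return mapping, (cat.names[best], float(per[best]))


def aggregate_by_mix(pred: PredictionBatch) -> PredictionBatch:
    """Mix-level predictions: arithmetic mean of each mix's image predictions.

    The mean of simplex vectors is itself on the simplex.  The returned batch
    has one row per mix_id, with sample_idx = photo_idx = -1.
    """
    if not len(pred):
        raise ValueError("empty prediction batch")
    g = (
        pred.rows.groupby("mix_id")[pred.weight_columns]
        .mean()
        .reset_index()
        .sort_values("mix_id")
        .reset_index(drop=True)
    )
    g["sample_idx"] = -1
    g["photo_idx"] = -1
    return PredictionBatch(g, pred.catalog)


@dataclass
class MetricsReport:
    """The four headline metrics plus the per-category breakdown."""

    mae: float
    mse: float
    r2: float | None
    per_seed_mae: dict[str, float]
    max_mae_seed: tuple[str, float]
    level: str
    n_rows: int = 0

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mse": self.mse,
            "r2": self.r2,
            "per_seed_mae": self.per_seed_mae,
            "max_mae_seed": {"label": self.max_mae_seed[0], "value": self.max_mae_seed[1]},
            "level": self.level,
            "n_rows": self.n_rows,
        }

    def table(self) -> str:
        r2 = f"{self.r2:.4f}" if self.r2 is not None else "undefined"
        lab, v = self.max_mae_seed
        return (
            f"{'MAE':>8} {'MSE':>8} {'R² score':>9} {'Max MAE/seed':>22}\n"
            f"{self.mae:>8.4f} {self.mse:>8.4f} {r2:>9} {f'{v:.4f} ({lab})':>22}"
        )


def metrics_report(pred: PredictionBatch, truth, level: str = "image") -> MetricsReport:
    """Compute all four metrics at image or mix level.

    At mix level the predictions are first averaged per mix and compared with
    the mix-level truth (mean of per-sample realized compositions).
    """
    if level == "mix":
        pred = aggregate_by_mix(pred)
    try:
        r2 = r2_score(pred, truth, level)
    except UndefinedMetricError:
        r2 = None
    per, mx = per_seed_mae(pred, truth, level=level)
    return MetricsReport(
        mae=mae(pred, truth, level),
        mse=mse(pred, truth, level),
        r2=r2,
        per_seed_mae=per,
        max_mae_seed=mx,
        level=level,
        n_rows=len(pred),
    )


def simulate_noisy_predictions(
    manifest: MixManifest, noise_std: float, rng: np.random.Generator
) -> PredictionBatch:
    """Predictions = truth + i.i.d. zero-mean Gaussian noise, projected back
    onto the simplex (Euclidean projection).

    A model-free stand-in for per-image prediction error, used to study how
    mix-level averaging of multiple photos of the same mix suppresses
    image-level noise.
    """
    t = manifest.weights_array()
    noisy = t + rng.normal(0.0, noise_std, size=t.shape)
    proj = sparsemax(noisy)  # Euclidean projection onto the simplex
    df = manifest.rows[list(KEY_COLUMNS)].copy()
    for j, c in enumerate(manifest.weight_columns):
        df[c] = proj[:, j]
    return PredictionBatch(df, manifest.catalog)
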