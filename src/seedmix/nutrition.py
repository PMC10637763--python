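"""Nutritional value of a seed mix from its composition.

The nutritional unit is the milk fodder unit per kilogram of dry matter
(MFU/kgDM): the net energy a ruminant can draw from the feed for lactation or
maintenance, with 1 MFU = 1,700 kcal.  A mix's value is the weighted mean of
the per-variety values, weighted by the mix's weight fractions.

The default per-variety table is the one distributed with the open Carpeso
seed-mix image dataset (Zenodo, DOI 10.5281/zenodo.8169473); it covers the 11
named varieties only, so the residual "other" mass is renormalized away before
conversion (debris has no tabulated feed value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .catalog import CompositionVector, renormalize_known
from .evaluation import MetricsReport, aggregate_by_mix
from .manifest import MixManifest, PredictionBatch

__all__ = [
    "KCAL_PER_MFU",
    "NutritionTable",
    "default_nutrition_table",
    "composition_to_mfu",
    "mfu_to_kcal",
    "nutrition_report",
]

logger = logging.getLogger(__name__)

KCAL_PER_MFU = 1700.0

#: MFU/kgDM of the 11 cataloged varieties
_DEFAULT_MFU = {
    "barley": 1.09,
    "faba_bean": 1.26,
    "forage_peas": 1.25,
    "lupine": 1.34,
    "oats": 0.99,
    "protein_peas": 1.25,
    "rye": 1.19,
    "spelt": 0.93,
    "triticale": 1.17,
    "vetch": 1.26,
    "wheat": 1.19,
}


@dataclass(frozen=True)
class NutritionTable:
    """Variety -> MFU/kgDM mapping plus the MFU->kcal constant."""

    mfu_per_kgdm: dict[str, float]
    kcal_per_mfu: float = KCAL_PER_MFU

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.mfu_per_kgdm.values()):
            raise ValueError("MFU values must be positive")

    def __getitem__(self, label: str) -> float:
        return self.mfu_per_kgdm[label]

    @property
    def min(self) -> float:
        return min(self.mfu_per_kgdm.values())

    @property
    def max(self) -> float:
        return max(self.mfu_per_kgdm.values())


def default_nutrition_table() -> NutritionTable:
    """The tabulated MFU/kgDM values for the 11 canonical varieties."""
    return NutritionTable(dict(_DEFAULT_MFU))


def composition_to_mfu(
    comp: CompositionVector, table: NutritionTable | None = None
) -> float:
    """Weighted combination of per-variety MFU values: ``sum_v w_v * mfu_v``.

    If the composition includes the residual "other" category it is first
    renormalized over the known varieties (the table has no entry for debris);
    a composition that is entirely residual raises.  The result always lies
    within [min, max] of the table.
    """
    table = table or default_nutrition_table()
    if comp.catalog.includes_other:
        if comp.other_weight > 0.15:
            logger.warning(
                "residual 'other' fraction %.2f > 0.15; MFU is extrapolated from "
                "the known varieties only",
                comp.other_weight,
            )
        comp = renormalize_known(comp)
    missing = [n for n, w in comp.as_dict().items() if w > 0 and n not in table.mfu_per_kgdm]
    if missing:
        raise KeyError(f"no MFU value for varieties {missing}")
    return float(
        sum(w * table.mfu_per_kgdm[n] for n, w in comp.as_dict().items() if w > 0)
    )


def mfu_to_kcal(mfu: float, table: NutritionTable | None = None) -> float:
    """Convert MFU to kcal (1 MFU = 1,700 kcal by default)."""
    k = (table or default_nutrition_table()).kcal_per_mfu
    return float(mfu) * k


def _mfu_series(batch_rows, wcols, catalog, table) -> np.ndarray:
    from .catalog import validate_composition

    out = np.empty(len(batch_rows))
    arr = batch_rows[wcols].to_numpy(dtype=float)
    for i, row in enumerate(arr):
        comp = validate_composition(row, catalog, tol=1e-4)
        out[i] = composition_to_mfu(comp, table)
    return out


def nutrition_report(
    pred: PredictionBatch,
    truth: MixManifest,
    table: NutritionTable | None = None,
    level: str = "image",
) -> MetricsReport:
    """MAE / MSE / R² on the scalar MFU series derived from compositions.

    At mix level, per-image predictions are averaged per mix *before*
    conversion.  Conversion is linear in the renormalized composition, so
    converting-then-averaging equals averaging-then-converting whenever the
    "other" fraction is identical across a mix's images; with unequal residual
    fractions the two differ by at most ``(max-min MFU) * spread(other)``.
    """
    table = table or default_nutrition_table()
    if level == "mix":
        pred = aggregate_by_mix(pred)
        tdf = truth.mix_truth()
        keys = ["mix_id"]
    else:
        tdf = truth.rows
        keys = ["mix_id", "sample_idx", "photo_idx"]
    merged = pred.rows.merge(tdf, on=keys, how="outer",
                             suffixes=("_pred", "_true"), indicator=True)
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        raise KeyError(f"{len(orphans)} unmatched rows between predictions and truth")
    wcols = pred.weight_columns
    p = _mfu_series(merged.rename(columns={f"{c}_pred": c for c in wcols}),
                    wcols, pred.catalog, table)
    t = _mfu_series(merged.rename(columns={f"{c}_true": c for c in wcols}),
                    wcols, truth.catalog, table)
    err = p - t
    mae_v = float(np.abs(err).mean())
    mse_v = float((err**2).mean())
    ss_tot = float(((t - t.mean()) ** 2).sum())
    r2 = None if ss_tot == 0 else 1.0 - float((err**2).sum()) / ss_tot
    return MetricsReport(
        mae=mae_v,
        mse=mse_v,
        r2=r2,
        per_seed_mae={},
        max_mae_seed=("", 0.0),
        level=level,
        n_rows=len(p),
    )
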