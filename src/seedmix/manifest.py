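"""Dataset manifest I/O, leakage-free splitting, and augmentation config.

The manifest CSV is the spine of a seed-mix image dataset: one row per photo,
keyed by ``(mix_id, sample_idx, photo_idx)``, carrying the image path,
optional campaign metadata (year, mix type) and the ground-truth weight
fractions as ``w_<label>`` columns.

Splitting is done at the *mix* level: all photos of one mix land on the same
side of the train/validation split.  Photos of the same physical mix are
near-duplicates, so an image-level split would leak validation content into
training and produce overly optimistic scores.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .catalog import (
    CompositionError,
    CompositionVector,
    VarietyCatalog,
    validate_composition,
)

__all__ = [
    "KEY_COLUMNS",
    "MixManifest",
    "PredictionBatch",
    "SplitResult",
    "read_manifest",
    "write_manifest",
    "split_by_mix",
    "augmentation_config",
    "AugmentationConfig",
    "AUGMENTATION_POLICIES",
]

KEY_COLUMNS = ("mix_id", "sample_idx", "photo_idx")
_META_COLUMNS = KEY_COLUMNS + ("image_path", "year", "mix_type")


def _weight_columns(catalog: VarietyCatalog) -> list[str]:
    return [f"w_{n}" for n in catalog.names]


@dataclass
class MixManifest:
    """Table linking mix -> sample -> image file -> ground-truth composition."""

    rows: pd.DataFrame
    catalog: VarietyCatalog

    def __post_init__(self) -> None:
        df = self.rows.reset_index(drop=True)
        wcols = _weight_columns(self.catalog)
        missing = [c for c in (*_META_COLUMNS, *wcols) if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        df = df[list(_META_COLUMNS) + wcols].copy()
        df["mix_id"] = df["mix_id"].astype(str)
        df["sample_idx"] = df["sample_idx"].astype(int)
        df["photo_idx"] = df["photo_idx"].astype(int)
        if df.duplicated(list(KEY_COLUMNS)).any():
            dupes = df[df.duplicated(list(KEY_COLUMNS), keep=False)]
            raise ValueError(
                f"duplicate (mix_id, sample_idx, photo_idx) keys:\n{dupes[list(KEY_COLUMNS)]}"
            )
        for i, row in enumerate(df[wcols].to_numpy(dtype=float)):
            try:
                validate_composition(row, self.catalog, tol=1e-4)
            except CompositionError as exc:
                raise CompositionError(f"manifest row {i}: {exc}") from exc
        self.rows = df

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def weight_columns(self) -> list[str]:
        return _weight_columns(self.catalog)

    @property
    def mix_ids(self) -> list[str]:
        return sorted(self.rows["mix_id"].unique())

    @property
    def n_mixes(self) -> int:
        return self.rows["mix_id"].nunique()

    def weights_array(self) -> np.ndarray:
        return self.rows[self.weight_columns].to_numpy(dtype=float)

    def composition(self, i: int) -> CompositionVector:
        return validate_composition(
            self.rows.loc[i, self.weight_columns].to_numpy(dtype=float),
            self.catalog,
            tol=1e-4,
        )

    def subset(self, mask) -> "MixManifest":
        return MixManifest(self.rows[mask].reset_index(drop=True), self.catalog)

    def mix_truth(self) -> pd.DataFrame:
        """Mix-level ground truth: mean of per-sample realized compositions.

        Samples of one mix differ only by count-rounding, so the mean is the
        natural mix-level target.  Returns one row per mix_id.
        """
        per_sample = (
            self.rows.groupby(["mix_id", "sample_idx"])[self.weight_columns]
            .mean()
            .reset_index()
        )
        return (
            per_sample.groupby("mix_id")[self.weight_columns]
            .mean()
            .reset_index()
            .sort_values("mix_id")
            .reset_index(drop=True)
        )

    @classmethod
    def from_rows(cls, records, catalog: VarietyCatalog) -> "MixManifest":
        """Build from dicts that may carry a ``composition`` CompositionVector."""
        flat = []
        for r in records:
            r = dict(r)
            comp = r.pop("composition", None)
            if comp is not None:
                for n, v in comp.as_dict().items():
                    r[f"w_{n}"] = v
            r.setdefault("year", None)
            r.setdefault("mix_type", "")
            flat.append(r)
        return cls(pd.DataFrame(flat), catalog)


def write_manifest(manifest: MixManifest, path) -> None:
    """Write the manifest CSV (comma-separated, UTF-8, weights to 6 decimals)."""
    df = manifest.rows.copy()
    for c in manifest.weight_columns:
        df[c] = df[c].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False, encoding="utf-8")


def read_manifest(path, tol: float = 1e-4) -> MixManifest:
    """Read a manifest CSV, inferring the catalog from the ``w_*`` header.

    Raises a schema error when no weight columns are present and a per-row
    validation error (citing the CSV line) when a row's weights are off the
    simplex by more than ``tol``.
    """
    df = pd.read_csv(path, encoding="utf-8")
    wcols = [c for c in df.columns if c.startswith("w_")]
    if not wcols:
        raise ValueError(f"{path}: no w_<label> weight columns in header")
    names = tuple(c[2:] for c in wcols)
    catalog = VarietyCatalog(names, includes_other=names[-1] == "other")
    for c in ("year",):
        if c in df.columns:
            df[c] = df[c].astype("Int64")
    if "mix_type" in df.columns:
        df["mix_type"] = df["mix_type"].fillna("")
    for i, row in enumerate(df[wcols].to_numpy(dtype=float)):
        try:
            validate_composition(row, catalog, tol=tol)
        except CompositionError as exc:
            # +2: header line and 1-based numbering
            raise CompositionError(f"{path} line {i + 2}: {exc}") from exc
    return MixManifest(df, catalog)


@dataclass
class PredictionBatch:
    """Per-image predicted compositions keyed like the manifest."""

    rows: pd.DataFrame
    catalog: VarietyCatalog

    def __post_init__(self) -> None:
        df = self.rows.reset_index(drop=True)
        wcols = _weight_columns(self.catalog)
        missing = [c for c in (*KEY_COLUMNS, *wcols) if c not in df.columns]
        if missing:
            raise ValueError(f"prediction batch missing columns: {missing}")
        df["mix_id"] = df["mix_id"].astype(str)
        self.rows = df[list(KEY_COLUMNS) + wcols].copy()

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def weight_columns(self) -> list[str]:
        return _weight_columns(self.catalog)

    def weights_array(self) -> np.ndarray:
        return self.rows[self.weight_columns].to_numpy(dtype=float)

    def validate(self, tol: float = 1e-5) -> None:
        for i, row in enumerate(self.weights_array()):
            try:
                validate_composition(row, self.catalog, tol=tol)
            except CompositionError as exc:
                raise CompositionError(f"prediction row {i}: {exc}") from exc

    def write(self, path) -> None:
        self.rows.to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def read(cls, path) -> "PredictionBatch":
        df = pd.read_csv(path, encoding="utf-8")
        wcols = [c for c in df.columns if c.startswith("w_")]
        names = tuple(c[2:] for c in wcols)
        return cls(df, VarietyCatalog(names, includes_other=names[-1] == "other"))


@dataclass(frozen=True)
class SplitResult:
    """Mix-level train/validation partition of a manifest."""

    train_mix_ids: tuple[str, ...]
    val_mix_ids: tuple[str, ...]
    train_rows: MixManifest
    val_rows: MixManifest

    def write(self, path) -> None:
        df = pd.DataFrame(
            [(m, "train") for m in self.train_mix_ids]
            + [(m, "val") for m in self.val_mix_ids],
            columns=["mix_id", "side"],
        )
        df.to_csv(path, index=False)


def split_by_mix(
    manifest: MixManifest, val_fraction: float = 0.2, seed: int = 0
) -> SplitResult:
    """Random 80/20-style split whose unit is the mix, not the image.

    Validation mix count is ``round(val_fraction * n_mixes)``, at least 1.
    Mix ids are sorted before shuffling, so the split depends only on the set
    of mixes and the seed, never on manifest row order.
    """
    if not (0 < val_fraction < 1):
        raise ValueError("val_fraction must be in (0, 1)")
    mixes = manifest.mix_ids
    n = len(mixes)
    if n < 2:
        raise ValueError("need at least 2 mixes to split")
    n_val = max(1, round(val_fraction * n))
    if n_val >= n:
        raise ValueError(
            f"val_fraction {val_fraction} leaves no training mixes ({n_val}/{n})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_ids = tuple(sorted(mixes[i] for i in perm[:n_val]))
    train_ids = tuple(sorted(mixes[i] for i in perm[n_val:]))
    val_mask = manifest.rows["mix_id"].isin(val_ids)
    return SplitResult(
        train_mix_ids=train_ids,
        val_mix_ids=val_ids,
        train_rows=manifest.subset(~val_mask),
        val_rows=manifest.subset(val_mask),
    )


# ---------------------------------------------------------------------------
# augmentation configuration

#: policy name -> default parameters
AUGMENTATION_POLICIES = {
    "center_crop": {},
    "random_rotation": {"degrees": 180},
    "color_jitter": {"brightness": 0.2, "contrast": 0.2, "saturation": 0.2},
    "auto_contrast": {},
    "randaugment": {"magnitude": 9, "magnitude_std": 0.5},
    "autoaugment": {"policy": "V0"},
}


@dataclass(frozen=True)
class AugmentationConfig:
    """Ordered, serializable description of the training-time augmentations.

    Validation images never go through this: they receive only the
    deterministic resize + center crop of the model's preprocessing.
    """

    policies: tuple[tuple[str, dict], ...]

    def describe(self) -> list[str]:
        out = []
        for name, params in self.policies:
            if name == "randaugment":
                out.append(
                    f"rand-m{params['magnitude']}-mstd{params['magnitude_std']}"
                )
            elif name == "autoaugment":
                out.append(f"autoaugment policy {params['policy']}")
            elif params:
                args = ",".join(f"{k}={v}" for k, v in sorted(params.items()))
                out.append(f"{name}({args})")
            else:
                out.append(name)
        return out

    def to_dict(self) -> dict:
        return {"policies": [[n, dict(p)] for n, p in self.policies]}

    def __bool__(self) -> bool:
        return bool(self.policies)

    def apply(self, img, rng: np.random.Generator):
        """Apply the configured policies to a PIL image (training only)."""
        from . import _augment_ops

        for name, params in self.policies:
            img = _augment_ops.apply_policy(img, name, params, rng)
        return img


def augmentation_config(spec) -> AugmentationConfig:
    """Build an :class:`AugmentationConfig` from named policies.

    ``spec`` is a list whose items are policy names or ``(name, params)``
    pairs; valid names are ``center_crop``, ``random_rotation``,
    ``color_jitter``, ``auto_contrast``, ``randaugment``, ``autoaugment``.
    An empty spec yields the identity transform.
    """
    policies = []
    for item in spec:
        if isinstance(item, str):
            name, params = item, {}
        else:
            name, params = item
        if name not in AUGMENTATION_POLICIES:
            raise ValueError(
                f"unknown augmentation policy {name!r}; valid: "
                f"{sorted(AUGMENTATION_POLICIES)}"
            )
        merged = {**AUGMENTATION_POLICIES[name], **dict(params)}
        policies.append((name, merged))
    return AugmentationConfig(tuple(policies))
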