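"""Composition-regression model: backbone features + a trained score head.

The model maps a photograph of a seed mix to a score vector ``z`` (one score
per catalog category) and converts scores to a composition on the simplex
with either a softmax head (trained with KL divergence) or a sparsemax head
(trained with the sparsemax loss).  The API follows the statsmodels pattern:

>>> model = CompositionRegression(split, backbone="tiny_cnn", loss="kldiv",
...                               image_root=data_dir)
>>> res = model.fit(TrainConfig(max_epochs=20, seed=0))
>>> print(res.summary())
>>> batch = res.predict(split.val_rows)

Backbones are pluggable behind :class:`BackboneSpec`.  The default desk-scale
backbone, ``tiny_cnn``, is a deterministic random-feature convolutional
extractor (fixed seeded filters over image patches, plus pooled color
statistics) with a trainable linear score head — small enough to train on one
CPU in seconds.  Large pretrained classification backbones
(EfficientNet-B4-ns at 380 px, BeiT-base at 384 px, BeiT-large at 512 px) are
registered under the same contract but require a GPU deep-learning runtime
and pretrained weights, which this package does not ship; building them
raises with that explanation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .catalog import VarietyCatalog
from .losses import LOSSES
from .manifest import (
    KEY_COLUMNS,
    AugmentationConfig,
    MixManifest,
    PredictionBatch,
    SplitResult,
)

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "BackboneUnavailableError",
    "BACKBONES",
    "TinyConvFeatures",
    "CompositionRegression",
    "CompositionRegressionResults",
    "build_model",
    "train",
    "predict_images",
    "load_results",
]

logger = logging.getLogger(__name__)

_FILTER_SEED = 0x5EED  # architecture constant: fixes the random filter bank


class BackboneUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackboneSpec:
    """Contract a feature extractor fulfils: name, input side, feature width."""

    name: str
    input_px: int
    out_dim: int
    default_lr: float = 0.05
    runnable: bool = True


class TinyConvFeatures:
    """Deterministic random-feature convolutional extractor, 128 px input.

    Preprocessing: resize the shorter side to ``input_px``, center crop.
    Features: 8x8 patches of the 64x64-downsampled crop are projected through
    a fixed Gaussian filter bank (seeded once, an architecture constant, never
    retrained) with ReLU, then mean- and max-pooled over patches; concatenated
    with a 4x4x4 RGB histogram and global color mean/std.  Only the linear
    score head on top of these features is trained.
    """

    input_px = 128
    _pool_px = 64
    _patch = 8
    _n_filters = 48

    def __init__(self) -> None:
        rng = np.random.default_rng(_FILTER_SEED)
        dim = self._patch * self._patch * 3
        self._filters = rng.standard_normal((dim, self._n_filters)) / np.sqrt(dim)

    @property
    def out_dim(self) -> int:
        return 2 * self._n_filters + 64 + 6

    def preprocess(self, img: Image.Image) -> Image.Image:
        img = img.convert("RGB")
        w, h = img.size
        s = self.input_px / min(w, h)
        img = img.resize((max(1, round(w * s)), max(1, round(h * s))), Image.BILINEAR)
        w, h = img.size
        left, top = (w - self.input_px) // 2, (h - self.input_px) // 2
        return img.crop((left, top, left + self.input_px, top + self.input_px))

    def __call__(self, img: Image.Image) -> np.ndarray:
        img = self.preprocess(img)
        small = np.asarray(
            img.resize((self._pool_px, self._pool_px), Image.BILINEAR), dtype=float
        ) / 255.0
        p = self._patch
        n = self._pool_px // p
        patches = (
            small.reshape(n, p, n, p, 3).swapaxes(1, 2).reshape(n * n, p * p * 3)
        )
        h = np.maximum(patches @ self._filters, 0.0)
        conv = np.concatenate([h.mean(axis=0), h.max(axis=0)])
        full = np.asarray(img, dtype=float) / 255.0
        bins = np.clip((full * 4).astype(int), 0, 3)
        idx = bins[..., 0] * 16 + bins[..., 1] * 4 + bins[..., 2]
        hist = np.bincount(idx.ravel(), minlength=64).astype(float)
        hist /= hist.sum()
        stats = np.concatenate([full.mean(axis=(0, 1)), full.std(axis=(0, 1))])
        return np.concatenate([conv, hist, stats])


def _tiny_cnn_spec() -> BackboneSpec:
    return BackboneSpec("tiny_cnn", input_px=128,
                        out_dim=TinyConvFeatures().out_dim, default_lr=0.05)


#: registered backbones; the GPU-scale pretrained ones are declared but not
#: runnable in this package
BACKBONES: dict[str, BackboneSpec] = {
    "tiny_cnn": _tiny_cnn_spec(),
    "efficientnet_b4_ns": BackboneSpec(
        "efficientnet_b4_ns", input_px=380, out_dim=1792,
        default_lr=5e-5, runnable=False),
    "beit_base_384": BackboneSpec(
        "beit_base_384", input_px=384, out_dim=768,
        default_lr=5e-5, runnable=False),
    "beit_large_512": BackboneSpec(
        "beit_large_512", input_px=512, out_dim=1024,
        default_lr=5e-5, runnable=False),
}


def _make_extractor(name: str) -> TinyConvFeatures:
    if name not in BACKBONES:
        raise ValueError(
            f"unknown backbone {name!r}; registered: {sorted(BACKBONES)}"
        )
    spec = BACKBONES[name]
    if not spec.runnable:
        raise BackboneUnavailableError(
            f"backbone {name!r} ({spec.input_px} px) is a GPU-scale pretrained "
            "architecture; it needs a deep-learning runtime and pretrained "
            "weights, neither of which this package ships. Use 'tiny_cnn'."
        )
    return TinyConvFeatures()


@dataclass(frozen=True)
class TrainConfig:
    """SGD training hyperparameters.

    The defaults mirror common settings for fine-tuning large pretrained
    backbones on this task — SGD, reduce-on-plateau scheduling with
    patience 5, batch size 10 — with the learning rate scaled per backbone:
    ``lr=None`` resolves to the backbone's registered default (5e-5 for the
    large pretrained architectures at batch 10; 0.05 for the tiny desk
    backbone, whose trainable part is a linear head on standardized
    features).
    """

    lr: float | None = None
    batch_size: int = 10
    max_epochs: int = 30
    patience: int = 5
    lr_factor: float = 0.1
    seed: int = 0
    optimizer: str = "sgd"

    def __post_init__(self) -> None:
        if self.lr is not None and self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.batch_size < 1 or self.patience < 1:
            raise ValueError("batch_size and patience must be >= 1")


class CompositionRegression:
    """Composition-regression model over a mix-level train/validation split.

    Parameters
    ----------
    split
        :class:`~seedmix.manifest.SplitResult` providing train and validation
        manifests (or any object with ``train_rows``/``val_rows``).
    backbone
        Registered backbone name; ``tiny_cnn`` is the CPU-trainable default.
    loss
        ``"kldiv"`` (softmax head) or ``"sparsemax"`` (sparsemax head).
        Heads and losses are paired, never mixed.
    image_root
        Directory that manifest image paths are relative to.
    augment
        Optional :class:`AugmentationConfig` applied to *training* images
        only; validation always gets the deterministic resize + center crop.
    """

    def __init__(
        self,
        split: SplitResult,
        backbone: str = "tiny_cnn",
        loss: str = "kldiv",
        image_root=None,
        augment: AugmentationConfig | None = None,
    ) -> None:
        if loss not in LOSSES:
            raise ValueError(f"loss must be one of {sorted(LOSSES)}")
        if not len(split.train_rows) or not len(split.val_rows):
            raise ValueError("both sides of the split must be nonempty")
        self.split = split
        self.backbone = backbone
        self.loss = loss
        self.image_root = Path(image_root) if image_root else Path(".")
        self.augment = augment
        self.catalog: VarietyCatalog = split.train_rows.catalog
        self._extractor = _make_extractor(backbone)

    @classmethod
    def from_manifest(
        cls,
        manifest: MixManifest,
        val_fraction: float = 0.2,
        split_seed: int = 0,
        **kwargs,
    ) -> "CompositionRegression":
        from .manifest import split_by_mix

        return cls(split_by_mix(manifest, val_fraction, split_seed), **kwargs)

    # ------------------------------------------------------------------
    def _features(self, manifest: MixManifest, rng=None) -> np.ndarray:
        feats = np.empty((len(manifest), self._extractor.out_dim))
        for i, rel in enumerate(manifest.rows["image_path"]):
            with Image.open(self.image_root / rel) as img:
                img = img.convert("RGB")
                if rng is not None and self.augment:
                    img = self.augment.apply(img, rng)
                feats[i] = self._extractor(img)
        return feats

    def fit(self, config: TrainConfig | None = None) -> "CompositionRegressionResults":
        """Train the score head with minibatch SGD; returns the results object.

        Deterministic given ``config.seed``.  The best checkpoint is the epoch
        with the lowest validation image-level MAE; the scheduler multiplies
        the learning rate by ``lr_factor`` when validation MAE has not
        improved for ``patience`` consecutive epochs.
        """
        config = config or TrainConfig()
        lr = config.lr if config.lr is not None else BACKBONES[self.backbone].default_lr
        rng = np.random.default_rng(config.seed)
        loss_fn, grad_fn, head = LOSSES[self.loss]

        y_train = self.split.train_rows.weights_array()
        y_val = self.split.val_rows.weights_array()
        x_train = self._features(self.split.train_rows,
                                 rng=rng if self.augment else None)
        x_val = self._features(self.split.val_rows)

        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd < 1e-8] = 1.0
        xt = (x_train - mu) / sd
        xv = (x_val - mu) / sd

        d, f = len(self.catalog), xt.shape[1]
        w = np.zeros((f, d))
        b = np.zeros(d)

        history = []
        best = {"mae": np.inf, "epoch": -1, "w": w.copy(), "b": b.copy()}
        stall = 0
        n = len(xt)
        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            n_batches = 0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                xb, qb = xt[idx], y_train[idx]
                z = xb @ w + b
                ep_loss += loss_fn(z, qb)
                gz = grad_fn(z, qb)  # (batch, d), already mean-scaled
                w -= lr * (xb.T @ gz)
                b -= lr * gz.sum(axis=0)
                n_batches += 1
            ep_loss /= n_batches
            if not np.isfinite(ep_loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}; lower the learning "
                    f"rate (current {lr:g})"
                )
            pv = head(xv @ w + b)
            val_mae = float(np.abs(pv - y_val).mean())
            history.append(
                {"epoch": epoch, "train_loss": ep_loss, "val_mae": val_mae, "lr": lr}
            )
            if val_mae < best["mae"] - 1e-6:
                best = {"mae": val_mae, "epoch": epoch, "w": w.copy(), "b": b.copy()}
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    lr *= config.lr_factor
                    stall = 0
                    logger.info("epoch %d: plateau, lr -> %g", epoch, lr)

        return CompositionRegressionResults(
            model=self,
            config=config,
            weights=best["w"],
            bias=best["b"],
            scaler=(mu, sd),
            history=pd.DataFrame(history),
            best_epoch=best["epoch"],
            best_val_mae=best["mae"],
        )


class CompositionRegressionResults:
    """Fitted composition-regression model: parameters, history, diagnostics."""

    def __init__(self, model, config, weights, bias, scaler, history,
                 best_epoch, best_val_mae) -> None:
        self.model = model
        self.config = config
        self.weights = weights
        self.bias = bias
        self.scaler = scaler
        self.history = history
        self.best_epoch = best_epoch
        self.best_val_mae = best_val_mae
        self.catalog: VarietyCatalog = model.catalog
        self.backbone: str = model.backbone
        self.loss: str = model.loss
        self._extractor = model._extractor

    # ------------------------------------------------------------------
    def predict(self, rows: MixManifest, image_root=None) -> PredictionBatch:
        """Per-image predicted compositions for the given manifest rows.

        Images get the deterministic resize + center crop, never augmentation.
        Unreadable images are collected and reported at the end; their rows
        are dropped from the batch.
        """
        root = Path(image_root) if image_root else self.model.image_root
        mu, sd = self.scaler
        _, _, head = LOSSES[self.loss]
        feats, kept, errors = [], [], []
        for i, rel in enumerate(rows.rows["image_path"]):
            try:
                with Image.open(root / rel) as img:
                    feats.append(self._extractor(img.convert("RGB")))
                kept.append(i)
            except OSError as exc:
                errors.append((rel, str(exc)))
        if errors:
            warnings.warn(
                f"{len(errors)} image(s) unreadable and skipped: "
                + "; ".join(f"{p}: {m}" for p, m in errors[:5]),
                stacklevel=2,
            )
        if not kept:
            return PredictionBatch(
                pd.DataFrame(columns=[*KEY_COLUMNS, *rows.weight_columns]),
                self.catalog,
            )
        x = (np.asarray(feats) - mu) / sd
        p = head(x @ self.weights + self.bias)
        df = rows.rows.iloc[kept][list(KEY_COLUMNS)].reset_index(drop=True)
        for j, c in enumerate(rows.weight_columns):
            df[c] = p[:, j]
        return PredictionBatch(df, self.catalog)

    def evaluate(self, rows: MixManifest | None = None, level: str = "image"):
        """Metrics report on the given rows (default: the validation split)."""
        from .evaluation import metrics_report

        rows = rows if rows is not None else self.model.split.val_rows
        return metrics_report(self.predict(rows), rows, level=level)

    def summary(self) -> str:
        """Text summary in the style of a fitted-model report."""
        rep = self.evaluate()
        lines = [
            "Composition regression results",
            "=" * 46,
            f"backbone:        {self.backbone}",
            f"loss / head:     {self.loss}",
            f"categories:      {len(self.catalog)}",
            f"train images:    {len(self.model.split.train_rows)} "
            f"({len(self.model.split.train_mix_ids)} mixes)",
            f"val images:      {len(self.model.split.val_rows)} "
            f"({len(self.model.split.val_mix_ids)} mixes)",
            f"epochs run:      {len(self.history)} (best: {self.best_epoch})",
            f"best val MAE:    {self.best_val_mae:.4f}",
            "",
            "Validation metrics (image level)",
            rep.table(),
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training-loss / validation-MAE curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train loss")
        ax.plot(self.history["epoch"], self.history["val_mae"], label="val MAE")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    def plot_per_seed_mae(self, rows=None, ax=None):
        """Bar chart of per-category MAE on the validation rows."""
        import matplotlib.pyplot as plt

        rep = self.evaluate(rows)
        if ax is None:
            _, ax = plt.subplots()
        labels = list(rep.per_seed_mae)
        ax.bar(labels, [rep.per_seed_mae[k] for k in labels])
        ax.set_ylabel("MAE")
        ax.tick_params(axis="x", rotation=60)
        return ax

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Single-file JSON checkpoint: weights + config + catalog + scaler."""
        payload = {
            "format": "seedmix-checkpoint-v1",
            "backbone": self.backbone,
            "loss": self.loss,
            "catalog": {
                "names": list(self.catalog.names),
                "includes_other": self.catalog.includes_other,
            },
            "config": {
                "lr": self.config.lr,
                "batch_size": self.config.batch_size,
                "max_epochs": self.config.max_epochs,
                "patience": self.config.patience,
                "lr_factor": self.config.lr_factor,
                "seed": self.config.seed,
            },
            "best_epoch": self.best_epoch,
            "best_val_mae": self.best_val_mae,
            "weights": self.weights.tolist(),
            "bias": self.bias.tolist(),
            "scaler_mean": self.scaler[0].tolist(),
            "scaler_std": self.scaler[1].tolist(),
            "history": self.history.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload))


class _LoadedModel:
    """Minimal stand-in for the model attribute of loaded results."""

    def __init__(self, catalog, backbone, loss, image_root):
        self.catalog = catalog
        self.backbone = backbone
        self.loss = loss
        self.image_root = Path(image_root) if image_root else Path(".")
        self._extractor = _make_extractor(backbone)


def load_results(path, image_root=None) -> CompositionRegressionResults:
    """Load a checkpoint written by :meth:`CompositionRegressionResults.save`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "seedmix-checkpoint-v1":
        raise ValueError(f"{path}: not a seedmix checkpoint")
    catalog = VarietyCatalog(
        tuple(payload["catalog"]["names"]), payload["catalog"]["includes_other"]
    )
    model = _LoadedModel(catalog, payload["backbone"], payload["loss"], image_root)
    cfg = TrainConfig(**payload["config"])
    res = CompositionRegressionResults.__new__(CompositionRegressionResults)
    res.model = model
    res.config = cfg
    res.weights = np.asarray(payload["weights"])
    res.bias = np.asarray(payload["bias"])
    res.scaler = (
        np.asarray(payload["scaler_mean"]),
        np.asarray(payload["scaler_std"]),
    )
    res.history = pd.DataFrame(payload["history"])
    res.best_epoch = payload["best_epoch"]
    res.best_val_mae = payload["best_val_mae"]
    res.catalog = catalog
    res.backbone = payload["backbone"]
    res.loss = payload["loss"]
    res._extractor = model._extractor
    return res


# ---------------------------------------------------------------------------
# functional wrappers

def build_model(
    backbone: str | BackboneSpec,
    catalog: VarietyCatalog,
    head: str = "softmax",
    **kwargs,
):
    """Return an unfitted model factory bound to a backbone and head.

    ``head="softmax"`` pairs with the KL-divergence loss, ``head="sparsemax"``
    with the sparsemax loss.  The returned callable takes a
    :class:`SplitResult` (plus keyword options) and yields a
    :class:`CompositionRegression`.
    """
    name = backbone.name if isinstance(backbone, BackboneSpec) else backbone
    _make_extractor(name)  # fail fast on unknown/unrunnable backbones
    loss = {"softmax": "kldiv", "sparsemax": "sparsemax"}.get(head, head)
    if loss not in LOSSES:
        raise ValueError(f"head must be 'softmax' or 'sparsemax', got {head!r}")

    def factory(split: SplitResult, **inner) -> CompositionRegression:
        opts = {**kwargs, **inner}
        m = CompositionRegression(split, backbone=name, loss=loss, **opts)
        if m.catalog.names != catalog.names:
            raise ValueError("split catalog does not match the model catalog")
        return m

    return factory


def train(model, split: SplitResult | None = None,
          config: TrainConfig | None = None,
          augment: AugmentationConfig | None = None,
          checkpoint_path=None) -> CompositionRegressionResults:
    """Fit a model (or model factory) and optionally save a checkpoint."""
    if callable(model) and not isinstance(model, CompositionRegression):
        if split is None:
            raise ValueError("a split is required to train a model factory")
        model = model(split, augment=augment)
    elif augment is not None:
        model.augment = augment
    res = model.fit(config)
    if checkpoint_path is not None:
        res.save(checkpoint_path)
    return res


def predict_images(results_or_checkpoint, rows: MixManifest,
                   image_root=None) -> PredictionBatch:
    """Predict per-image compositions from fitted results or a checkpoint file."""
    if isinstance(results_or_checkpoint, (str, Path)):
        results = load_results(results_or_checkpoint, image_root=image_root)
    else:
        results = results_or_checkpoint
    return results.predict(rows, image_root=image_root)
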