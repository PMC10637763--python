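"""Reusable desk-scale experiments.

The parameter-recovery experiment is the package's standing check that the
whole pipeline works: render a synthetic dataset whose ground truth is exact
by construction, split it at the mix level, train the desk backbone, and
measure how well the known compositions are recovered on held-out mixes.

Study conditions (defaults): 40 mixes over the 6 high-contrast varieties,
1–4 varieties per mix, 5 samples x 5 photos per mix (the standard acquisition
protocol), 128 px renders, SGD with reduce-on-plateau (patience 5) at the
desk backbone's learning rate.  The sparsemax head is the default objective
here: with a linear score head its loss gradient (sparsemax(z) − target)
makes training a projected least-squares fit, which matches the MAE metric;
the KL objective weights relative error instead and needs a deep backbone to
shine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import VarietyCatalog
from .manifest import MixManifest, SplitResult, split_by_mix
from .model import CompositionRegression, CompositionRegressionResults, TrainConfig
from .render import (
    RenderConfig,
    high_contrast_profiles,
    random_mix_specs,
    render_dataset,
)

__all__ = ["RecoveryRun", "render_recovery_dataset", "run_recovery"]


@dataclass
class RecoveryRun:
    """One trained recovery experiment and its artifacts."""

    manifest: MixManifest
    split: SplitResult
    results: CompositionRegressionResults
    image_dir: str


def render_recovery_dataset(
    out_dir,
    dataset_seed: int = 1,
    n_mixes: int = 40,
    samples_per_mix: int = 5,
    photos_per_sample: int = 5,
    image_px: int = 128,
    total_mass_g: float = 12.0,
    n_varieties_range: tuple[int, int] = (1, 4),
) -> MixManifest:
    """Render the recovery dataset: 6 high-contrast varieties, 5x5 protocol."""
    profiles = high_contrast_profiles()
    labels = tuple(profiles)
    catalog = VarietyCatalog(labels)
    rng = np.random.default_rng(dataset_seed)
    specs = random_mix_specs(
        n_mixes, labels, rng, catalog=catalog, n_varieties_range=n_varieties_range
    )
    config = RenderConfig(image_px=image_px, seed=dataset_seed)
    return render_dataset(
        specs,
        profiles,
        config,
        out_dir,
        samples_per_mix=samples_per_mix,
        photos_per_sample=photos_per_sample,
        total_mass_g=total_mass_g,
        overwrite=True,
    )


def run_recovery(
    image_dir,
    manifest: MixManifest,
    train_seed: int = 0,
    split_seed: int = 0,
    loss: str = "sparsemax",
    max_epochs: int = 15,
    val_fraction: float = 0.2,
) -> RecoveryRun:
    """Split, train and return the fitted recovery experiment."""
    split = split_by_mix(manifest, val_fraction=val_fraction, seed=split_seed)
    model = CompositionRegression(split, loss=loss, image_root=image_dir)
    results = model.fit(TrainConfig(max_epochs=max_epochs, seed=train_seed))
    return RecoveryRun(
        manifest=manifest, split=split, results=results, image_dir=str(image_dir)
    )
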