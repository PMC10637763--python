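"""Shared test helpers: programmatic manifest construction."""

import numpy as np
import pandas as pd

from seedmix.catalog import VarietyCatalog
from seedmix.manifest import MixManifest, PredictionBatch


def make_manifest(n_mixes=10, photos_per_mix=3, catalog=None, seed=0, years=None):
    """Random valid manifest with one sample per mix (no images on disk)."""
    cat = catalog or VarietyCatalog.default()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_mixes):
        w = rng.dirichlet(np.ones(len(cat)))
        for p in range(photos_per_mix):
            rows.append(
                {
                    "mix_id": f"m{i:03d}",
                    "sample_idx": 0,
                    "photo_idx": p,
                    "image_path": f"m{i:03d}_{p}.png",
                    "year": None if years is None else years[i % len(years)],
                    "mix_type": "composition",
                    **{f"w_{n}": w[j] for j, n in enumerate(cat.names)},
                }
            )
    return MixManifest(pd.DataFrame(rows), cat)


def batch_from_manifest(m: MixManifest, weights=None) -> PredictionBatch:
    """Prediction batch carrying the manifest's own (or given) weights."""
    df = m.rows[["mix_id", "sample_idx", "photo_idx"]].copy()
    w = m.weights_array() if weights is None else np.asarray(weights)
    for j, c in enumerate(m.weight_columns):
        df[c] = w[:, j]
    return PredictionBatch(df, m.catalog)
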