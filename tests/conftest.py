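"""Shared fixtures: catalogs and a session-scoped recovery experiment.

The rendered recovery dataset and the two trained models (sparsemax and
softmax/KL heads) are expensive enough to build once and share across test
modules; everything is seeded so the suite is deterministic.
"""

import numpy as np
import pytest

from seedmix.catalog import VarietyCatalog
from seedmix.experiments import render_recovery_dataset, run_recovery


@pytest.fixture(scope="session")
def default_catalog():
    return VarietyCatalog.default()


@pytest.fixture(scope="session")
def recovery_dataset(tmp_path_factory):
    """40 synthetic mixes, 6 high-contrast varieties, 5 samples x 5 photos."""
    out = tmp_path_factory.mktemp("recovery_images")
    manifest = render_recovery_dataset(out, dataset_seed=1)
    return out, manifest


@pytest.fixture(scope="session")
def recovery_run(recovery_dataset):
    """Sparsemax-head recovery model trained with seed 0."""
    image_dir, manifest = recovery_dataset
    return run_recovery(image_dir, manifest, train_seed=0, loss="sparsemax")


@pytest.fixture(scope="session")
def recovery_run_kldiv(recovery_dataset):
    """Softmax/KL-head model on the same split, for head comparisons."""
    image_dir, manifest = recovery_dataset
    return run_recovery(image_dir, manifest, train_seed=0, loss="kldiv")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
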