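import numpy as np
import pandas as pd
import pytest

from seedmix.catalog import VarietyCatalog, validate_composition
from seedmix.manifest import MixManifest, SplitResult, split_by_mix
from seedmix.model import (
    BACKBONES,
    BackboneUnavailableError,
    CompositionRegression,
    TinyConvFeatures,
    TrainConfig,
    build_model,
    load_results,
    predict_images,
)
from seedmix.render import RenderConfig, render_dataset

@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    """Tiny rendered dataset (6 mixes, 2x2 protocol) for fast model tests."""
    from seedmix.render import high_contrast_profiles, random_mix_specs

    out = tmp_path_factory.mktemp("small_images")
    profiles = high_contrast_profiles()
    labels = tuple(profiles)
    cat = VarietyCatalog(labels)
    rng = np.random.default_rng(5)
    specs = random_mix_specs(6, labels, rng, catalog=cat, n_varieties_range=(1, 3))
    cfg = RenderConfig(image_px=128, seed=5)
    manifest = render_dataset(specs, profiles, cfg, out, samples_per_mix=2,
                              photos_per_sample=2, total_mass_g=10.0)
    return out, manifest


class TestBackbones:
    def test_unknown_backbone_lists_registered(self, small_dataset):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        with pytest.raises(ValueError, match="tiny_cnn"):
            CompositionRegression(sp, backbone="resnet9000", image_root=out)

    def test_gpu_scale_backbones_registered_but_unavailable(self, small_dataset):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        for name in ("efficientnet_b4_ns", "beit_base_384", "beit_large_512"):
            assert name in BACKBONES
            with pytest.raises(BackboneUnavailableError):
                CompositionRegression(sp, backbone=name, image_root=out)

    def test_pretrained_backbone_input_resolutions(self):
        assert BACKBONES["efficientnet_b4_ns"].input_px == 380
        assert BACKBONES["beit_base_384"].input_px == 384
        assert BACKBONES["beit_large_512"].input_px == 512
        assert BACKBONES["tiny_cnn"].input_px == 128

    def test_feature_extractor_deterministic(self):
        from PIL import Image

        rng = np.random.default_rng(0)
        img = Image.fromarray(rng.integers(0, 255, (140, 150, 3), dtype=np.uint8))
        ex1, ex2 = TinyConvFeatures(), TinyConvFeatures()
        np.testing.assert_array_equal(ex1(img), ex2(img))


class TestHeads:
    def test_output_shape_and_simplex(self, small_dataset):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        for loss in ("kldiv", "sparsemax"):
            res = CompositionRegression(sp, loss=loss, image_root=out).fit(
                TrainConfig(max_epochs=2, seed=0)
            )
            pred = res.predict(sp.val_rows)
            w = pred.weights_array()
            assert w.shape == (len(sp.val_rows), len(manifest.catalog))
            for row in w:
                validate_composition(row, manifest.catalog, tol=1e-5)

    def test_sparsemax_head_yields_exact_zeros_softmax_does_not(self, rng):
        from seedmix.losses import softmax, sparsemax

        z = rng.normal(0, 2, (100, 6))
        assert (sparsemax(z) == 0).sum() > 0
        assert (softmax(z) > 0).all()


class TestTraining:
    def test_one_epoch_bookkeeping_and_checkpoint(self, small_dataset, tmp_path):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        res = CompositionRegression(sp, image_root=out).fit(
            TrainConfig(max_epochs=1, seed=0)
        )
        assert len(res.history) == 1
        ckpt = tmp_path / "ckpt.json"
        res.save(ckpt)
        assert ckpt.exists()

    def test_same_seed_identical_history(self, small_dataset):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        r1 = CompositionRegression(sp, image_root=out).fit(TrainConfig(max_epochs=3, seed=9))
        r2 = CompositionRegression(sp, image_root=out).fit(TrainConfig(max_epochs=3, seed=9))
        pd.testing.assert_frame_equal(r1.history, r2.history)

    def test_single_image_overfit_loss_decreases(self, small_dataset):
        """Sanity: training loss on one repeated image drops monotonically."""
        out, manifest = small_dataset
        row = manifest.rows.iloc[[0]].copy()
        repeated = []
        for i in range(8):
            r = row.copy()
            r["photo_idx"] = i
            repeated.append(r)
        train_m = MixManifest(pd.concat(repeated), manifest.catalog)
        val_m = manifest.subset(manifest.rows["mix_id"] == manifest.mix_ids[-1])
        sp = SplitResult(
            (train_m.mix_ids[0],), tuple(val_m.mix_ids), train_m, val_m
        )
        res = CompositionRegression(sp, loss="sparsemax", image_root=out).fit(
            TrainConfig(max_epochs=5, seed=0, batch_size=8)
        )
        losses = res.history["train_loss"].to_numpy()
        assert (np.diff(losses) <= 1e-12).all()

    def test_empty_split_side_rejected(self, small_dataset):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        empty = manifest.subset(manifest.rows["mix_id"] == "nope")
        with pytest.raises(ValueError, match="nonempty"):
            CompositionRegression(
                SplitResult(sp.train_mix_ids, (), sp.train_rows, empty),
                image_root=out,
            )


class TestPrediction:
    def test_predict_twice_identical(self, small_dataset):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        res = CompositionRegression(sp, image_root=out).fit(TrainConfig(max_epochs=2, seed=0))
        p1 = res.predict(sp.val_rows)
        p2 = res.predict(sp.val_rows)
        np.testing.assert_array_equal(p1.weights_array(), p2.weights_array())

    def test_empty_rows_empty_batch(self, small_dataset):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        res = CompositionRegression(sp, image_root=out).fit(TrainConfig(max_epochs=1, seed=0))
        empty = manifest.subset(manifest.rows["mix_id"] == "nope")
        assert len(res.predict(empty)) == 0

    def test_unreadable_image_warns_and_continues(self, small_dataset, tmp_path):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        res = CompositionRegression(sp, image_root=out).fit(TrainConfig(max_epochs=1, seed=0))
        rows = sp.val_rows.rows.copy()
        rows.loc[rows.index[0], "image_path"] = "missing.png"
        broken = MixManifest(rows, manifest.catalog)
        with pytest.warns(UserWarning, match="unreadable"):
            batch = res.predict(broken)
        assert len(batch) == len(rows) - 1

    def test_checkpoint_round_trip_predicts_identically(self, small_dataset, tmp_path):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        res = CompositionRegression(sp, image_root=out).fit(TrainConfig(max_epochs=2, seed=0))
        ckpt = tmp_path / "ckpt.json"
        res.save(ckpt)
        loaded = load_results(ckpt, image_root=out)
        np.testing.assert_allclose(
            loaded.predict(sp.val_rows).weights_array(),
            res.predict(sp.val_rows).weights_array(),
            atol=1e-12,
        )
        batch = predict_images(ckpt, sp.val_rows, image_root=out)
        assert len(batch) == len(sp.val_rows)

    def test_build_model_factory_contract(self, small_dataset):
        out, manifest = small_dataset
        sp = split_by_mix(manifest, 0.2, seed=0)
        factory = build_model("tiny_cnn", manifest.catalog, head="sparsemax")
        model = factory(sp, image_root=out)
        assert model.loss == "sparsemax"
        with pytest.raises(ValueError, match="head"):
            build_model("tiny_cnn", manifest.catalog, head="argmax")


class TestSummary:
    def test_summary_mentions_metrics_and_setup(self, recovery_run):
        text = recovery_run.results.summary()
        assert "MAE" in text and "tiny_cnn" in text and "sparsemax" in text
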