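import numpy as np
import pytest

from seedmix.catalog import VarietyCatalog, validate_composition
from seedmix.render import (
    OverfullBoxError,
    RenderConfig,
    VarietyProfile,
    high_contrast_profiles,
    preset_profiles,
    random_mix_specs,
    render_dataset,
    render_sample,
    weights_to_counts,
)


def _profiles(masses, labels=("a", "b")):
    colors = [(200, 40, 40), (40, 200, 40), (40, 40, 200)]
    return {
        lab: VarietyProfile(
            label=lab, mean_axis_px=18.0, axis_cv=0.1, base_color=colors[i % 3],
            color_jitter=5.0, per_seed_mass_g=m,
        )
        for i, (lab, m) in enumerate(zip(labels, masses))
    }


class TestWeightsToCounts:
    def test_exact_division(self):
        cat = VarietyCatalog(("a", "b"))
        comp = validate_composition([0.5, 0.5], cat)
        r = weights_to_counts(comp, 10.0, _profiles([0.05, 0.05]))
        assert r.counts == {"a": 100, "b": 100}
        np.testing.assert_allclose(r.realized_composition.weights, [0.5, 0.5])

    def test_largest_remainder_hand_case(self):
        cat = VarietyCatalog(("a", "b"))
        comp = validate_composition([0.6, 0.4], cat)
        r = weights_to_counts(comp, 1.0, _profiles([0.1, 0.1]))
        assert r.counts == {"a": 6, "b": 4}
        np.testing.assert_allclose(r.realized_composition.weights, [0.6, 0.4])

    def test_monocrop_identity(self):
        cat = VarietyCatalog(("a", "b"))
        comp = validate_composition([1.0, 0.0], cat)
        r = weights_to_counts(comp, 3.3, _profiles([0.05, 0.05]))
        assert set(r.counts) == {"a"}
        np.testing.assert_allclose(r.realized_composition.weights, [1.0, 0.0])

    def test_missing_profile_for_nonzero_weight_errors(self):
        cat = VarietyCatalog(("a", "b"))
        comp = validate_composition([0.5, 0.5], cat)
        with pytest.raises(ValueError, match="no profile"):
            weights_to_counts(comp, 10.0, _profiles([0.05], labels=("a",)))

    def test_too_small_mass_warns_and_reflects_zero_count(self):
        cat = VarietyCatalog(("a", "b"))
        comp = validate_composition([0.97, 0.03], cat)
        with pytest.warns(UserWarning, match="too small"):
            r = weights_to_counts(comp, 1.0, _profiles([0.05, 0.9]))
        assert r.counts["b"] == 0
        assert r.realized_composition["b"] == 0.0

    def test_other_mass_kept_continuous_without_profile(self):
        cat = VarietyCatalog(("a", "other"), includes_other=True)
        comp = validate_composition([0.9, 0.1], cat)
        r = weights_to_counts(comp, 10.0, _profiles([0.05], labels=("a",)))
        assert r.realized_composition["other"] == pytest.approx(0.1, abs=1e-9)

    def test_equal_masses_realized_matches_count_fractions(self, rng):
        """With equal per-seed masses, weight fractions equal count fractions."""
        cat = VarietyCatalog(("a", "b", "c"))
        profs = _profiles([0.05, 0.05, 0.05], labels=("a", "b", "c"))
        for _ in range(50):
            w = rng.dirichlet(np.ones(3))
            comp = validate_composition(w, cat, tol=1e-9)
            r = weights_to_counts(comp, 20.0, profs)
            total = sum(r.counts.values())
            for i, lab in enumerate(("a", "b", "c")):
                assert abs(r.counts[lab] / total - w[i]) <= 1.0 / total + 1e-12

    def test_realized_composition_is_validatable_at_tight_tolerance(self, rng):
        cat = VarietyCatalog(("a", "b", "c"))
        profs = _profiles([0.04, 0.2, 0.5], labels=("a", "b", "c"))
        for _ in range(30):
            comp = validate_composition(rng.dirichlet(np.ones(3)), cat, tol=1e-9)
            r = weights_to_counts(comp, 25.0, profs)
            validate_composition(r.realized_composition.weights, cat, tol=1e-9)


class TestRenderSample:
    def setup_method(self):
        self.cat = VarietyCatalog(("a", "b"))
        self.profiles = _profiles([0.05, 0.08])
        self.comp = validate_composition([0.5, 0.5], self.cat)
        self.config = RenderConfig(image_px=96, seed=7)
        self.realization = weights_to_counts(self.comp, 1.0, self.profiles)

    def test_same_inputs_bit_identical(self):
        img1, _ = render_sample(self.realization, self.profiles, self.config, 0, "m", 0)
        img2, _ = render_sample(self.realization, self.profiles, self.config, 0, "m", 0)
        assert np.array_equal(np.asarray(img1), np.asarray(img2))

    def test_shake_changes_placement_not_counts(self):
        _, meta0 = render_sample(self.realization, self.profiles, self.config, 0, "m", 0)
        _, meta1 = render_sample(self.realization, self.profiles, self.config, 1, "m", 0)
        assert len(meta0["placement"]) == len(meta1["placement"])
        c0 = [p["center"] for p in meta0["placement"]]
        c1 = [p["center"] for p in meta1["placement"]]
        assert c0 != c1

    def test_all_seed_centers_inside_box(self):
        _, meta = render_sample(self.realization, self.profiles, self.config, 0, "m", 0)
        cx = cy = self.config.image_px / 2
        r = self.config.box_radius_frac * self.config.image_px
        for p in meta["placement"]:
            x, y = p["center"]
            assert (x - cx) ** 2 + (y - cy) ** 2 <= r**2 + 1e-9

    def test_empty_counts_renders_plain_box(self):
        empty = weights_to_counts(self.comp, 1.0, self.profiles)
        empty.counts = {"a": 0, "b": 0}
        img, meta = render_sample(empty, self.profiles, self.config, 0, "m", 0)
        assert meta["placement"] == []
        # no seed colors present: only background/box shades (greys) plus noise
        arr = np.asarray(img).astype(int)
        assert np.abs(arr[..., 0] - arr[..., 1]).mean() < 30

    def test_overfull_box_raises(self):
        cat = VarietyCatalog(("a",))
        comp = validate_composition([1.0], cat)
        profs = _profiles([0.001], labels=("a",))
        fat = weights_to_counts(comp, 50.0, profs)  # 50000 seeds
        with pytest.raises(OverfullBoxError, match="overfull"):
            render_sample(fat, profs, self.config, 0, "m", 0)


class TestRenderDataset:
    def test_five_by_five_protocol_counts(self, tmp_path, rng):
        profiles = high_contrast_profiles()
        labels = tuple(profiles)
        cat = VarietyCatalog(labels)
        specs = random_mix_specs(4, labels, rng, catalog=cat,
                                 n_varieties_range=(1, 3))
        cfg = RenderConfig(image_px=64, seed=3)
        m = render_dataset(specs, profiles, cfg, tmp_path, total_mass_g=5.0)
        assert len(m) == 4 * 5 * 5
        assert len(list(tmp_path.glob("*.png"))) == 100

    def test_single_image_manifest_matches_realized(self, tmp_path):
        cat = VarietyCatalog(("a", "b"))
        comp = validate_composition([0.6, 0.4], cat)
        profs = _profiles([0.1, 0.1])
        cfg = RenderConfig(image_px=64, seed=3)
        m = render_dataset([("m0", comp)], profs, cfg, tmp_path,
                           samples_per_mix=1, photos_per_sample=1,
                           total_mass_g=1.0)
        assert len(m) == 1
        np.testing.assert_allclose(m.weights_array()[0], [0.6, 0.4], atol=1e-12)

    def test_collision_without_overwrite_errors(self, tmp_path):
        cat = VarietyCatalog(("a",))
        comp = validate_composition([1.0], cat)
        profs = _profiles([0.1], labels=("a",))
        cfg = RenderConfig(image_px=64, seed=3)
        args = ([("m0", comp)], profs, cfg, tmp_path)
        kw = dict(samples_per_mix=1, photos_per_sample=1, total_mass_g=1.0)
        render_dataset(*args, **kw)
        with pytest.raises(FileExistsError):
            render_dataset(*args, **kw)
        render_dataset(*args, overwrite=True, **kw)  # succeeds

    def test_duplicate_mix_ids_rejected(self, tmp_path):
        cat = VarietyCatalog(("a",))
        comp = validate_composition([1.0], cat)
        profs = _profiles([0.1], labels=("a",))
        cfg = RenderConfig(image_px=64, seed=3)
        with pytest.raises(ValueError, match="unique"):
            render_dataset([("m0", comp), ("m0", comp)], profs, cfg, tmp_path)


def test_preset_profiles_cover_all_12_categories():
    profs = preset_profiles()
    assert set(profs) == set(VarietyCatalog.default().names)
    assert profs["other"].shape == "debris"
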