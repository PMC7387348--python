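import math

import numpy as np
import pytest
from conftest import TRAIN_KWARGS, rasterize_disk

from cfoscount.overlap import (
    OverlapModel,
    count_in_contour,
    count_in_contour_fallback,
    make_patch,
    patchify,
    train_overlap_model,
)
from cfoscount.shapes import extract_contours
from cfoscount.synth import make_overlap_patch


class TestPatchify:
    def test_translation_removed_exactly(self):
        a = rasterize_disk(9, center=(15, 15), size=60)
        b = rasterize_disk(9, center=(40, 28), size=60)
        np.testing.assert_array_equal(patchify(a).pixels, patchify(b).pixels)

    def test_scaling_nearly_removed(self):
        base = rasterize_disk(12, size=40)
        doubled = rasterize_disk(24, size=80)
        pa = patchify(base).pixels
        pb = patchify(doubled).pixels
        agreement = (pa == pb).mean()
        assert agreement >= 0.98

    def test_make_patch_uses_contour_region_only(self):
        mask = rasterize_disk(8, center=(20, 20), size=64) | rasterize_disk(
            8, center=(50, 50), size=64
        )
        recs = extract_contours(mask)
        patch = make_patch(recs[0], mask)
        # the neighbouring object must not bleed into the patch: one blob only
        from scipy import ndimage

        _, n = ndimage.label(patch.pixels, np.ones((3, 3)))
        assert n == 1

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.zeros((10, 10), dtype=bool))


class TestGradients:
    def test_backprop_matches_numeric_gradient(self, rng):
        model = OverlapModel(seed=1)
        x = rng.random((2, 1, 32, 32)) - 0.5
        y = np.array([0, 3])
        _, grads = model.loss_and_grads(x, y)
        for name in ("w1", "b1", "w2", "w3", "b4"):
            p = model.params[name]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = model.loss_and_grads(x, y)
            p[idx] = orig - eps
            lm, _ = model.loss_and_grads(x, y)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(numeric, abs=1e-7, rel=1e-4)


class TestTraining:
    def test_reproducible_given_seed(self, overlap_model):
        again = train_overlap_model(**TRAIN_KWARGS)
        test_patches = np.stack(
            [make_overlap_patch(k, seed=100 + k)[0] for k in (1, 2, 3, 4)]
        )
        np.testing.assert_array_equal(
            overlap_model.predict(test_patches), again.predict(test_patches)
        )

    def test_single_class_data_rejected(self):
        patches = [(make_overlap_patch(1, seed=i)[0], 1) for i in range(30)]
        with pytest.raises(ValueError, match="per class"):
            train_overlap_model(patch_source=patches, seed=0)

    def test_bad_label_rejected(self):
        patches = [(np.zeros((64, 64), dtype=bool), 7)]
        with pytest.raises(ValueError, match="label"):
            train_overlap_model(patch_source=patches, seed=0)

    def test_holdout_accuracy_bars(self, overlap_model):
        acc = overlap_model.metadata["holdout_accuracy_per_class"]
        assert acc["1"] >= 0.90 and acc["2"] >= 0.90
        assert acc["3"] >= 0.80 and acc["4"] >= 0.80


class TestCounting:
    def test_untrained_model_raises(self):
        model = OverlapModel(seed=0)
        with pytest.raises(RuntimeError, match="not been trained"):
            model.predict(np.zeros((1, 64, 64), dtype=bool))

    def test_single_disk_counts_one(self, overlap_model):
        patch = patchify(rasterize_disk(12, size=40))
        assert count_in_contour(overlap_model, patch) == 1

    @pytest.mark.parametrize("k", [2, 3])
    def test_fused_disks_counted(self, overlap_model, k):
        hits = 0
        for seed in range(10):
            patch, label = make_overlap_patch(k, seed=3000 + seed)
            if count_in_contour(overlap_model, patchify(patch)) == label:
                hits += 1
        assert hits >= 8

    def test_degenerate_patch_counts_one_with_warning(self, overlap_model):
        tiny = np.zeros((64, 64), dtype=bool)
        tiny[30:32, 30:32] = True
        from cfoscount.overlap import ContourPatch

        with pytest.warns(UserWarning, match="degenerate"):
            assert count_in_contour(overlap_model, ContourPatch(tiny)) == 1

    def test_prediction_translation_invariant(self, overlap_model):
        a = rasterize_disk(10, center=(16, 16), size=80)
        b = rasterize_disk(10, center=(60, 44), size=80)
        (ra,) = extract_contours(a)
        (rb,) = extract_contours(b)
        assert count_in_contour(overlap_model, make_patch(ra)) == count_in_contour(
            overlap_model, make_patch(rb)
        )


class TestFallback:
    def test_arithmetic(self):
        rec = extract_contours(rasterize_disk(10))[0]
        rec.area = math.pi * 100  # exactly one nominal cell area
        assert count_in_contour_fallback(rec, 10, area_factor=1.5) == 1
        rec.area = 3 * math.pi * 100 * 1.5
        assert count_in_contour_fallback(rec, 10, area_factor=1.5) == 3

    def test_always_at_least_one(self):
        rec = extract_contours(rasterize_disk(3))[0]
        assert count_in_contour_fallback(rec, 50) == 1


class TestSerialization:
    def test_save_load_roundtrip(self, overlap_model, tmp_path):
        path = tmp_path / "model.npz"
        overlap_model.save(path)
        loaded = OverlapModel.load(path)
        patches = np.stack([make_overlap_patch(k, seed=77 + k)[0] for k in (1, 2, 3, 4)])
        np.testing.assert_array_equal(
            overlap_model.predict(patches), loaded.predict(patches)
        )
        assert loaded.metadata == overlap_model.metadata

    def test_version_mismatch_refused(self, overlap_model, tmp_path):
        path = tmp_path / "model.npz"
        overlap_model.save(path)
        data = dict(np.load(path))
        data["format"] = np.array("someone-elses-format")
        np.savez(path, **data)
        with pytest.raises(ValueError, match="format"):
            OverlapModel.load(path)

    def test_untrained_model_not_saved(self, tmp_path):
        with pytest.raises(RuntimeError):
            OverlapModel(seed=0).save(tmp_path / "m.npz")
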