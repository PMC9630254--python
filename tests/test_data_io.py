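"""Manifests, hold-out splits, fold plans, class weights, augmentations."""

import numpy as np
import pytest

from emseg.data_io import (ClassScheme, ClassWeights, DatasetManifest,
                           LabeledSample, ManifestError, augment_sample,
                           compute_class_weights, load_manifest, make_cv_folds,
                           save_manifest, split_holdout)
from emseg.synthetic import SynthConfig, generate_dataset


class TestClassScheme:
    def test_background_must_lead(self):
        with pytest.raises(ValueError):
            ClassScheme(("cytoplasm", "background"))

    def test_names_unique(self):
        with pytest.raises(ValueError):
            ClassScheme(("background", "a", "a"))

    def test_n_classes(self):
        assert ClassScheme(("background", "nucleus")).n_classes == 2


class TestManifest:
    def test_round_trip(self, phantom_dataset):
        manifest, out = phantom_dataset
        loaded = load_manifest(out / "manifest.csv")
        assert len(loaded) == 10
        assert loaded.scheme == manifest.scheme
        assert loaded.ids() == manifest.ids()
        orig = manifest.load(0)
        back = loaded.load(0)
        assert np.array_equal(orig.image, back.image)
        assert np.array_equal(orig.mask, back.mask)

    def test_missing_manifest(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_manifest(tmp_path / "nope.csv")

    def test_missing_mask_names_offender(self, phantom_dataset, tmp_path):
        manifest, out = phantom_dataset
        text = (out / "manifest.csv").read_text().replace(
            "phantom_0003_mask.png", "gone.png")
        bad = tmp_path / "manifest.csv"
        bad.write_text(text)
        (tmp_path / "manifest.yaml").write_text((out / "manifest.yaml").read_text())
        # image files are elsewhere; point a fresh copy at them
        text = text.replace("phantom_", f"{out}/phantom_").replace(
            f"{out}/phantom_0003_mask", f"{out}/gone")
        bad.write_text(text)
        with pytest.raises(ManifestError, match="phantom_0003"):
            load_manifest(bad)

    def test_duplicate_id_rejected(self, phantom_dataset, tmp_path):
        manifest, out = phantom_dataset
        lines = (out / "manifest.csv").read_text().splitlines()
        lines.append(lines[1])
        bad = tmp_path / "manifest.csv"
        bad.write_text("\n".join(
            line.replace("phantom_0", f"{out}/phantom_0", 1)
            if i > 0 else line
            for i, line in enumerate(lines)).replace(f"{out}/phantom_00,", ""))
        (tmp_path / "manifest.yaml").write_text((out / "manifest.yaml").read_text())
        with pytest.raises(ManifestError, match="duplicate"):
            load_manifest(bad)

    def test_mask_labels_out_of_range_rejected(self, phantom_dataset):
        manifest, _ = phantom_dataset
        sample = manifest.load(0)
        sample.mask[0, 0] = 7
        with pytest.raises(ManifestError, match="labels outside"):
            sample.validate(manifest.scheme.n_classes)


class TestSplitHoldout:
    @pytest.mark.parametrize("n,expected_train", [
        (323, 258),   # largest published dataset: 323 -> 258 + 65
        (135, 108),   # 135 -> 108 + 27
        (122, 97),
        (10, 8),
    ])
    def test_published_counts(self, n, expected_train, scheme3):
        manifest = _fake_manifest(n, scheme3)
        train, test = split_holdout(manifest, 0.8, seed=0)
        assert len(train) == expected_train
        assert len(test) == n - expected_train

    def test_partition_property(self, scheme3):
        """Disjoint, exhaustive, floor-rounded for every N in 2..400."""
        for n in range(2, 401):
            manifest = _fake_manifest(n, scheme3)
            train, test = split_holdout(manifest, 0.8, seed=n)
            assert len(train) == int(np.floor(0.8 * n))
            assert len(train) + len(test) == n
            assert not set(train.ids()) & set(test.ids())

    def test_deterministic(self, scheme3):
        m = _fake_manifest(50, scheme3)
        a = split_holdout(m, 0.8, seed=3)[0].ids()
        b = split_holdout(m, 0.8, seed=3)[0].ids()
        assert a == b
        c = split_holdout(m, 0.8, seed=4)[0].ids()
        assert a != c

    def test_too_small(self, scheme3):
        with pytest.raises(ValueError):
            split_holdout(_fake_manifest(1, scheme3))


def _fake_manifest(n, scheme):
    from pathlib import Path
    return DatasetManifest([(f"s{i}", Path(f"i{i}"), Path(f"m{i}"))
                            for i in range(n)], scheme)


class TestFoldPlan:
    def test_even_division(self, scheme3):
        plan = make_cv_folds(_fake_manifest(10, scheme3), k=5, repeats=1, seed=0)
        sizes = sorted(len(f) for f in plan.assignments[0])
        assert sizes == [2] * 5

    def test_remainder_balanced(self, scheme3):
        plan = make_cv_folds(_fake_manifest(11, scheme3), k=5, repeats=1, seed=0)
        sizes = sorted((len(f) for f in plan.assignments[0]), reverse=True)
        assert sizes == [3, 2, 2, 2, 2]

    def test_partition_and_reshuffle(self, scheme3):
        m = _fake_manifest(23, scheme3)
        plan = make_cv_folds(m, k=5, repeats=5, seed=1)
        for rep in range(5):
            flat = [x for fold in plan.assignments[rep] for x in fold]
            assert sorted(flat) == sorted(m.ids())
        assert plan.assignments[0] != plan.assignments[1]

    def test_deterministic(self, scheme3):
        m = _fake_manifest(17, scheme3)
        assert make_cv_folds(m, 5, 2, seed=9) == make_cv_folds(m, 5, 2, seed=9)

    def test_too_few_samples(self, scheme3):
        with pytest.raises(ValueError):
            make_cv_folds(_fake_manifest(3, scheme3), k=5)

    def test_folds_iterator_covers_all(self, scheme3):
        m = _fake_manifest(10, scheme3)
        plan = make_cv_folds(m, k=5, repeats=1, seed=0)
        for train_ids, val_ids in plan.folds(0):
            assert sorted(train_ids + val_ids) == sorted(m.ids())
            assert not set(train_ids) & set(val_ids)


class TestClassWeights:
    def test_inverse_frequency_hand_case(self, tmp_path, scheme3):
        # 90/10 pixel split over two classes -> weights (0.2, 1.8)
        mask = np.zeros((10, 10), np.int32)
        mask[0, :] = 1
        manifest = _write_single(tmp_path, mask, ("background", "nucleus"))
        w = compute_class_weights(manifest)
        assert w.weights == pytest.approx((0.2, 1.8))

    def test_equal_counts_all_ones(self, tmp_path):
        mask = np.zeros((2, 2), np.int32)
        mask[:, 1] = 1
        manifest = _write_single(tmp_path, mask, ("background", "nucleus"))
        assert compute_class_weights(manifest).weights == pytest.approx((1.0, 1.0))

    def test_missing_class_listed(self, tmp_path):
        mask = np.zeros((4, 4), np.int32)
        manifest = _write_single(tmp_path, mask, ("background", "nucleus"))
        with pytest.raises(ValueError, match="nucleus"):
            compute_class_weights(manifest)

    def test_mean_one_and_positive(self, phantom_dataset):
        manifest, _ = phantom_dataset
        w = compute_class_weights(manifest)
        assert np.mean(w.weights) == pytest.approx(1.0)
        assert all(x > 0 for x in w.weights)

    def test_validation(self):
        with pytest.raises(ValueError):
            ClassWeights((0.5, -0.5))
        with pytest.raises(ValueError):
            ClassWeights((2.0, 3.0))


def _write_single(tmp_path, mask, names):
    from emseg.data_io import save_sample
    img = np.full(mask.shape, 100, np.uint8)
    save_sample(LabeledSample("a", img, mask), tmp_path / "a.png",
                tmp_path / "a_mask.png")
    manifest = DatasetManifest([("a", tmp_path / "a.png",
                                 tmp_path / "a_mask.png")], ClassScheme(names))
    save_manifest(manifest, tmp_path / "manifest.csv")
    return load_manifest(tmp_path / "manifest.csv")


class TestAugmentations:
    def test_flip_involution(self, phantom_samples):
        s = phantom_samples[0]
        twice = augment_sample(augment_sample(s, "vertical_flip"), "vertical_flip")
        assert np.array_equal(twice.image, s.image)
        assert np.array_equal(twice.mask, s.mask)

    @pytest.mark.parametrize("op", ["vertical_flip", "horizontal_flip",
                                    "transpose"])
    def test_pixelcount_preserving_ops(self, phantom_samples, op):
        s = phantom_samples[1]
        out = augment_sample(s, op, seed=0)
        assert np.array_equal(np.bincount(out.mask.ravel(), minlength=3),
                              np.bincount(s.mask.ravel(), minlength=3))

    @pytest.mark.parametrize("op", ["random_rotate", "grid_distortion"])
    def test_resampling_ops_keep_label_alphabet_and_shape(self, phantom_samples,
                                                          op):
        s = phantom_samples[2]
        out = augment_sample(s, op, seed=3)
        assert out.image.shape == s.image.shape
        assert out.mask.shape == s.mask.shape
        assert set(np.unique(out.mask)) <= set(np.unique(s.mask))
        assert np.issubdtype(out.mask.dtype, np.integer)

    def test_deterministic_per_seed(self, phantom_samples):
        s = phantom_samples[3]
        a = augment_sample(s, "grid_distortion", seed=11)
        b = augment_sample(s, "grid_distortion", seed=11)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_unknown_op(self, phantom_samples):
        with pytest.raises(KeyError):
            augment_sample(phantom_samples[0], "zoom_blur")
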