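"""Dataset pipeline: indexing, splitting, balancing, augmentation, streams."""

import math
from pathlib import Path

import numpy as np
import pytest

from histonet import data as dm
from histonet import stain
from histonet.data import (BalancedTrainStream, ChannelStats, DatasetIndex,
                           EvalStream, GeometricParams, ImageRecord,
                           LayoutError, PipelineConfig, augmix,
                           draw_geometric_params, geometric_transform,
                           index_dataset, plan_balance, preprocess,
                           split_counts, standardize, stratified_split)
from histonet.synthetic import BREAKHIS_CLASS_COUNTS, BREAKHIS_CLASSES, reference_tile


def index_from_counts(counts: dict, magnification: int = 40) -> DatasetIndex:
    """Build an in-memory index from per-class counts (no files needed)."""
    records = [
        ImageRecord(Path(f"{c}/{c}_{i:05d}.png"), c, magnification)
        for c, n in counts.items() for i in range(n)
    ]
    return DatasetIndex(records, dict(counts), magnification, tuple(counts))


class TestIndex:
    def test_published_40x_counts_total(self, tmp_path):
        """A tree with the published 40x per-class file counts indexes to
        those counts and total 1995 (files only need to exist)."""
        counts = dict(zip(BREAKHIS_CLASSES, BREAKHIS_CLASS_COUNTS[40]))
        for cls, n in counts.items():
            d = tmp_path / "40" / cls
            d.mkdir(parents=True)
            for i in range(n):
                (d / f"{i:05d}.png").touch()
        idx = index_dataset(tmp_path, 40)
        assert idx.per_class_counts == counts
        assert len(idx.records) == 1995

    def test_one_image_per_class(self, tmp_path):
        for cls in ("A", "F"):
            d = tmp_path / "40" / cls
            d.mkdir(parents=True)
            (d / "x.png").touch()
        idx = index_dataset(tmp_path, 40, classes=("A", "F"))
        assert idx.per_class_counts == {"A": 1, "F": 1}

    def test_non_image_files_skipped(self, tmp_path):
        d = tmp_path / "40" / "A"
        d.mkdir(parents=True)
        (d / "a.png").touch()
        (d / "notes.txt").touch()
        (d / "thumbs.db").touch()
        idx = index_dataset(tmp_path, 40, classes=("A",))
        # oracle: directory listing filtered by the extension whitelist
        expected = [p for p in sorted(d.iterdir())
                    if p.suffix.lower() in dm.IMAGE_EXTENSIONS]
        assert [r.path for r in idx.records] == expected

    def test_missing_class_names_it(self, tmp_path):
        (tmp_path / "40" / "A").mkdir(parents=True)
        (tmp_path / "40" / "A" / "x.png").touch()
        with pytest.raises(LayoutError, match="'F'"):
            index_dataset(tmp_path, 40, classes=("A", "F"))

    def test_empty_class_rejected(self, tmp_path):
        (tmp_path / "40" / "A").mkdir(parents=True)
        with pytest.raises(LayoutError, match="no images"):
            index_dataset(tmp_path, 40, classes=("A",))

    def test_deterministic_sorted_enumeration(self, small_tree):
        root, _ = small_tree
        a = index_dataset(root, 40, classes=("A", "F", "DC"))
        b = index_dataset(root, 40, classes=("A", "F", "DC"))
        assert [r.path for r in a.records] == [r.path for r in b.records]
        per_class = [r.path for r in a.records if r.label == "A"]
        assert per_class == sorted(per_class)


class TestSplit:
    def test_floor_rounding_on_largest_40x_class(self):
        # 864 ductal-carcinoma images at 40x -> 604 train; consistency:
        # 3 x 604 must equal the balanced per-class target 1812
        train, val, test = split_counts(864)
        assert train == math.floor(0.7 * 864) == 604
        assert 3 * train == 1812
        assert train + val + test == 864

    def test_ten_images_split_7_2_1(self):
        assert split_counts(10) == (7, 2, 1)

    def test_split_determinism_and_leak_freedom(self, small_tree):
        root, _ = small_tree
        idx = index_dataset(root, 40, classes=("A", "F", "DC"))
        s1 = stratified_split(idx, seed=4)
        s2 = stratified_split(idx, seed=4)
        key = lambda s: sorted((str(r.path), r.split) for r in s.records)
        assert key(s1) == key(s2)
        parts = {name: {str(r.path) for r in s1.records if r.split == name}
                 for name in ("train", "val", "test")}
        assert not (parts["train"] & parts["val"])
        assert not (parts["train"] & parts["test"])
        assert not (parts["val"] & parts["test"])
        assert len(parts["train"] | parts["val"] | parts["test"]) == len(idx.records)

    def test_different_seed_different_membership(self, small_tree):
        root, _ = small_tree
        idx = index_dataset(root, 40, classes=("A", "F", "DC"))
        s1 = stratified_split(idx, seed=1)
        s2 = stratified_split(idx, seed=2)
        key = lambda s: sorted((str(r.path), r.split) for r in s.records)
        assert key(s1) != key(s2)

    def test_small_class_rejected(self):
        idx = index_from_counts({"A": 2, "F": 5})
        with pytest.raises(ValueError, match="A"):
            stratified_split(idx)

    def test_bad_ratios_rejected(self, small_tree):
        root, _ = small_tree
        idx = index_dataset(root, 40, classes=("A", "F", "DC"))
        with pytest.raises(ValueError):
            stratified_split(idx, ratios=(0.5, 0.2, 0.2))


class TestBalancePlan:
    def test_published_40x_plan(self):
        """From the published 40x counts: per-class train counts floor(0.7 n),
        max 604 (DC), target 1812, epoch length 14,496."""
        counts = dict(zip(BREAKHIS_CLASSES, BREAKHIS_CLASS_COUNTS[40]))
        idx = stratified_split(index_from_counts(counts), seed=0)
        plan = plan_balance(idx.subset("train"))
        assert plan.max_class_count == 604
        assert plan.oversample_target == 1812
        assert plan.epoch_length == 8 * 1812 == 14496
        assert plan.augment_with_mix["DC"] is False
        assert all(plan.augment_with_mix[c] for c in counts if c != "DC")

    def test_equal_classes_no_mix(self):
        idx = index_from_counts({"A": 5, "F": 5})
        plan = plan_balance(idx)
        assert plan.oversample_target == 15
        assert not any(plan.augment_with_mix.values())

    def test_two_class_brute_force(self):
        # counts (2, 3): max 3, target 9 each, only the class of 2 mixed
        idx = index_from_counts({"A": 2, "F": 3})
        plan = plan_balance(idx)
        assert plan.oversample_target == 9
        assert plan.epoch_length == 18
        assert plan.augment_with_mix == {"A": True, "F": False}

    def test_empty_split_rejected(self):
        idx = DatasetIndex([], {"A": 0}, 40, ("A",))
        with pytest.raises(ValueError):
            plan_balance(idx)


class TestStandardize:
    def test_identity_stats(self, rng):
        x = rng.random((4, 4, 3))
        out = standardize(x, ChannelStats(mean=(0, 0, 0), std=(1, 1, 1)))
        np.testing.assert_allclose(out, x)

    def test_constant_at_mean_is_zero(self):
        x = np.full((4, 4, 3), 0.5)
        out = standardize(x, ChannelStats(mean=(0.5, 0.5, 0.5), std=(2, 2, 2)))
        np.testing.assert_allclose(out, 0.0)

    def test_matches_per_pixel_loop(self, rng):
        x = rng.random((4, 4, 3))
        stats = ChannelStats(mean=(0.2, 0.4, 0.6), std=(0.5, 0.25, 2.0))
        out = standardize(x, stats)
        for h in range(4):
            for w in range(4):
                for c in range(3):
                    expected = (x[h, w, c] - stats.mean[c]) / stats.std[c]
                    assert abs(out[h, w, c] - expected) < 1e-12

    def test_zero_sigma_rejected_upstream(self):
        with pytest.raises(ValueError):
            ChannelStats(mean=(0, 0, 0), std=(1, 0, 1))


class TestPreprocess:
    def test_resize_and_crop_to_side(self, rng):
        img = rng.integers(0, 256, (70, 46, 3), dtype=np.uint8)
        assert preprocess(img, side=32).shape == (32, 32, 3)

    def test_square_input_unchanged_dims(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        out = preprocess(img, side=32)
        assert out.shape == (32, 32, 3)
        assert np.array_equal(out, img)  # no resampling when already sized

    def test_stain_normalized_output_matches_target(self, he_image):
        target = stain.fit_target(reference_tile(48))
        from histonet.synthetic import apply_stain_shift

        cast = apply_stain_shift(he_image, (-30, 20, 0))
        out = preprocess(cast, side=48, target=target)
        s = stain.compute_lab_stats(stain.rgb_to_lab(out))
        assert np.abs(s.mean - target.stats.mean).max() <= 1.0


class TestGeometricTransform:
    def test_identity_params_pixel_identical(self, he_image):
        params = GeometricParams(False, False, 0.0, (0.0, 0.0), 1.0, 0.0)
        out = geometric_transform(he_image, params=params)
        assert np.array_equal(out, he_image)

    def test_horizontal_flip_only_reverses_columns(self, he_image):
        params = GeometricParams(True, False, 0.0, (0.0, 0.0), 1.0, 0.0)
        out = geometric_transform(he_image, params=params)
        assert np.array_equal(out, he_image[:, ::-1])

    def test_vertical_flip_only_reverses_rows(self, he_image):
        params = GeometricParams(False, True, 0.0, (0.0, 0.0), 1.0, 0.0)
        out = geometric_transform(he_image, params=params)
        assert np.array_equal(out, he_image[::-1, :])

    def test_dimensions_preserved(self, he_image, rng):
        out = geometric_transform(he_image, rng=rng)
        assert out.shape == he_image.shape

    def test_parameter_ranges_monte_carlo(self):
        """10,000 draws: flip frequency inside the binomial 99% CI of 0.5;
        rotation/scale/shear/translation samples inside their ranges."""
        rng = np.random.default_rng(77)
        draws = [draw_geometric_params(rng) for _ in range(10_000)]
        hflips = sum(p.hflip for p in draws)
        # binomial(10000, .5): 99% CI half-width = 2.576 * sqrt(n)/2 ~ 129
        assert abs(hflips - 5000) < 129
        angles = [p.angle for p in draws]
        assert -45 <= min(angles) and max(angles) <= 45
        assert all(0.8 <= p.scale <= 1.2 for p in draws)
        assert all(0.0 <= p.shear <= 10.0 for p in draws)
        assert all(abs(p.translate[0]) <= 0.1 and abs(p.translate[1]) <= 0.1
                   for p in draws)


class TestAugmix:
    def test_severity_zero_is_identity(self, he_image):
        out = augmix(he_image, np.random.default_rng(0), severity=0)
        assert np.array_equal(out, he_image)

    def test_fixed_seed_bit_identical(self, he_image):
        a = augmix(he_image, np.random.default_rng(42))
        b = augmix(he_image, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_dirichlet_weights_on_simplex(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            w = rng.dirichlet([1.0] * 3)
            assert abs(w.sum() - 1.0) < 1e-9
            assert np.all(w >= 0)

    def test_output_same_shape_dtype(self, he_image):
        out = augmix(he_image, np.random.default_rng(5))
        assert out.shape == he_image.shape and out.dtype == np.uint8


class TestStreams:
    @pytest.fixture()
    def split_index(self, imbalanced_tree):
        root, _ = imbalanced_tree
        idx = index_dataset(root, 40, classes=("A", "F", "DC"))
        return stratified_split(idx, seed=0)

    @pytest.fixture()
    def pipe(self):
        return PipelineConfig(side=32, stain_target=None, use_stain_norm=False)

    def test_modulo_indexing(self, split_index, pipe):
        train = split_index.subset("train")
        plan = plan_balance(train)
        stream = BalancedTrainStream(train, plan, pipe, seed=0)
        cls = "DC"  # 7 train images
        n = len(stream.paths[cls])
        rng = np.random.default_rng(0)
        # position i loads image i mod n: compare pixels at i and i + n
        x1, _ = stream.get_item(cls, 1, np.random.default_rng(1))
        x2, _ = stream.get_item(cls, 1 + n, np.random.default_rng(1))
        np.testing.assert_array_equal(x1, x2)

    def test_out_of_range_position(self, split_index, pipe):
        train = split_index.subset("train")
        plan = plan_balance(train)
        stream = BalancedTrainStream(train, plan, pipe, seed=0)
        with pytest.raises(IndexError):
            stream.get_item("A", plan.oversample_target, np.random.default_rng(0))

    def test_epoch_conservation(self, split_index, pipe):
        """One epoch yields exactly oversample_target items per class."""
        train = split_index.subset("train")
        plan = plan_balance(train)
        stream = BalancedTrainStream(train, plan, pipe, seed=0)
        labels = [y for _, y in stream.epoch(0)]
        counts = np.bincount(labels, minlength=3)
        assert len(labels) == plan.epoch_length
        assert all(c == plan.oversample_target for c in counts)

    def test_majority_class_never_mixed(self, split_index, pipe):
        train = split_index.subset("train")
        plan = plan_balance(train)
        biggest = max(plan.class_counts, key=plan.class_counts.get)
        assert plan.augment_with_mix[biggest] is False

    def test_stream_determinism(self, split_index, pipe):
        train = split_index.subset("train")
        plan = plan_balance(train)
        s1 = BalancedTrainStream(train, plan, pipe, seed=3)
        s2 = BalancedTrainStream(train, plan, pipe, seed=3)
        for (x1, y1), (x2, y2) in zip(s1.epoch(0), s2.epoch(0)):
            np.testing.assert_array_equal(x1, x2)
            assert y1 == y2

    def test_eval_stream_is_untouched(self, split_index, pipe):
        """Validation items are preprocessing + standardization only:
        identical across iterations (no randomness) and in index order."""
        val = split_index.subset("val")
        stream = EvalStream(val, pipe)
        a = [x for x, _ in stream]
        b = [x for x, _ in stream]
        for x1, x2 in zip(a, b):
            np.testing.assert_array_equal(x1, x2)
        assert len(a) == len(val.records)

    def test_unbalanced_ablation_preserves_imbalance(self, split_index, pipe):
        from dataclasses import replace

        train = split_index.subset("train")
        plan = plan_balance(train)
        pipe2 = replace(pipe, use_balance_aug=False)
        stream = BalancedTrainStream(train, plan, pipe2, seed=0)
        labels = [y for _, y in stream.epoch(0)]
        counts = np.bincount(labels, minlength=3)
        # three geometric repetitions of each class's own count, unequal
        expected = np.array([3 * plan.class_counts[c] for c in stream.classes])
        np.testing.assert_array_equal(np.sort(counts), np.sort(expected))
        assert counts.min() != counts.max()
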