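"""Patient-level splits, augmentation, metrics, training protocol."""

import numpy as np
import pytest

import retispec as r
from retispec.classify import (AugmentationPolicy, ConfusionMatrix, SplitPlan,
                               TrainConfig, audit_no_leakage, augment,
                               compare_modalities, make_splits,
                               metrics_from_confusion, train_eval, transfer_recipe)


class TestSplits:
    def test_ten_subjects_split_7_1_2(self):
        cohort = r.make_cohort({"Normal": (10, 10)}, seed=0)
        (plan,) = make_splits(cohort, n_folds=1, seed=0)
        assert (len(plan.train), len(plan.val), len(plan.test)) == (7, 1, 2)

    def test_partitions_disjoint_and_exhaustive(self, tiny_cohort):
        plans = make_splits(tiny_cohort, n_folds=3, seed=1)
        all_subjects = set(tiny_cohort.subjects.subject_id)
        for plan in plans:
            union = set(plan.train) | set(plan.val) | set(plan.test)
            assert union == all_subjects
            assert not set(plan.train) & set(plan.test)
            assert not set(plan.train) & set(plan.val)

    def test_same_seed_reproduces_plans(self, tiny_cohort):
        a = make_splits(tiny_cohort, n_folds=2, seed=9)
        b = make_splits(tiny_cohort, n_folds=2, seed=9)
        assert a == b

    def test_stratified_by_group(self, tiny_cohort):
        (plan,) = make_splits(tiny_cohort, n_folds=1, seed=2)
        groups = tiny_cohort.subjects.set_index("subject_id")["group"]
        for part in (plan.test, plan.val):
            assert set(groups.loc[list(part)]) == set(r.GROUPS)

    def test_too_small_group_rejected(self):
        cohort = r.make_cohort({"Normal": (10, 10), "MCI": (3, 3)}, seed=0)
        with pytest.raises(ValueError, match="MCI"):
            make_splits(cohort, n_folds=1, seed=0)

    def test_leakage_audit_detects_duplicates(self):
        bad = SplitPlan(fold=0, train=("a", "b"), val=("b",), test=("c",))
        with pytest.raises(AssertionError):
            audit_no_leakage([bad])


class TestAugment:
    def test_disabled_policy_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 1, (16, 16, 3))
        off = AugmentationPolicy(hflip=False, vflip=False, rotation_deg=0,
                                 green_channel=False, noise_amp=0, opening_radius=0)
        assert np.array_equal(augment(img, off), img)

    def test_horizontal_flip_twice_is_identity(self):
        img = np.random.default_rng(1).uniform(0, 1, (16, 16, 3))
        assert np.array_equal(img[:, ::-1][:, ::-1], img)

    def test_rotation_round_trip(self):
        from skimage.transform import rotate

        yy, xx = np.mgrid[0:32, 0:32] / 32.0
        img = np.stack([0.5 + 0.3 * np.sin(4 * yy + c) * np.cos(3 * xx)
                        for c in range(3)], axis=2)
        back = rotate(rotate(img, 10, mode="edge"), -10, mode="edge")
        inner = (slice(8, 24), slice(8, 24))
        assert np.abs(back[inner] - img[inner]).mean() < 0.01

    def test_dims_and_range_preserved(self):
        img = np.random.default_rng(3).uniform(0, 1, (24, 24, 3))
        pol = AugmentationPolicy(noise_amp=0.05, opening_radius=1)
        out = augment(img, pol, np.random.default_rng(0))
        assert out.shape == img.shape
        assert out.min() >= 0 and out.max() <= 1

    def test_green_channel_extraction_replicates_middle_channel(self):
        img = np.random.default_rng(4).uniform(0, 1, (8, 8, 3))
        pol = AugmentationPolicy(hflip=False, vflip=False, rotation_deg=0,
                                 green_channel=True, noise_amp=0)
        # rng with first draw < 0.5 triggers the extraction
        out = augment(img, pol, np.random.default_rng(1))
        if not np.array_equal(out, img):
            assert np.array_equal(out[:, :, 0], out[:, :, 1])


class TestMetrics:
    def test_perfect_diagonal_gives_all_ones(self):
        from retispec.classify import CLASS_ORDER

        cm = ConfusionMatrix(np.diag([5, 7, 9]), CLASS_ORDER)
        m = metrics_from_confusion(cm)
        assert m.accuracy == 1.0
        assert (m.table[["precision", "recall", "specificity", "f1"]] == 1.0).all().all()

    def test_hand_enumerated_two_class_matrix(self):
        # [[5,1],[2,4]]: TP0=5, FN0=1, FP0=2, TN0=4
        cm = ConfusionMatrix(np.array([[5, 1], [2, 4]]), ("pos", "neg"))
        m = metrics_from_confusion(cm)
        assert m.accuracy == pytest.approx(0.75)
        assert m.table.loc["pos", "precision"] == pytest.approx(5 / 7)
        assert m.table.loc["pos", "recall"] == pytest.approx(5 / 6)
        assert m.table.loc["pos", "specificity"] == pytest.approx(4 / 6)
        p, q = 5 / 7, 5 / 6
        assert m.table.loc["pos", "f1"] == pytest.approx(2 * p * q / (p + q))

    def test_class_permutation_permutes_rows_not_accuracy(self):
        counts = np.array([[8, 2, 0], [1, 6, 3], [0, 2, 9]])
        m1 = metrics_from_confusion(ConfusionMatrix(counts, ("a", "b", "c")))
        perm = [2, 0, 1]
        m2 = metrics_from_confusion(
            ConfusionMatrix(counts[np.ix_(perm, perm)], ("c", "a", "b")))
        assert m1.accuracy == pytest.approx(m2.accuracy)
        for cls in ("a", "b", "c"):
            assert m1.table.loc[cls, "recall"] == pytest.approx(m2.table.loc[cls, "recall"])

    def test_undefined_ratio_reported_as_nan_not_zero(self):
        cm = ConfusionMatrix(np.array([[3, 0], [2, 0]]), ("a", "b"))
        m = metrics_from_confusion(cm)
        assert np.isnan(m.table.loc["b", "precision"])
        assert not (m.table.loc["b", "precision"] == 0)

    def test_support_weighted_recalls_sum_to_accuracy(self):
        counts = np.array([[8, 2, 1], [2, 6, 3], [1, 2, 9]])
        m = metrics_from_confusion(ConfusionMatrix(counts, ("a", "b", "c")))
        support = m.table["support"]
        weighted = (m.table["recall"] * support).sum() / support.sum()
        assert weighted == pytest.approx(m.accuracy)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(np.zeros((2, 2)), ("a", "b")))


def _separable_images(n_per_class, size=16, seed=0):
    rng = np.random.default_rng(seed)
    X, y, sids = [], [], []
    for i in range(n_per_class):
        for cls, level in (("Dementia", 0.75), ("Normal", 0.25)):
            img = np.full((size, size, 3), level) + rng.normal(0, 0.02, (size, size, 3))
            X.append(np.clip(img, 0, 1))
            y.append(cls)
            sids.append(f"{cls[0]}{i:02d}")
    return np.array(X), np.array(y), np.array(sids)


class TestTrainEval:
    def _plan(self, sids):
        subs = sorted(set(sids))
        d = [s for s in subs if s.startswith("D")]
        n = [s for s in subs if s.startswith("N")]
        return SplitPlan(fold=0, train=tuple(d[:-4] + n[:-4]),
                         val=tuple(d[-4:-2] + n[-4:-2]),
                         test=tuple(d[-2:] + n[-2:]))

    def test_linearly_separable_data_classified_accurately(self):
        X, y, sids = _separable_images(12)
        res = train_eval(X, y, sids, self._plan(sids), TrainConfig(seed=0))
        assert res.metrics.accuracy >= 0.95

    def test_deterministic_reruns_give_identical_confusions(self):
        X, y, sids = _separable_images(8)
        cfg = TrainConfig(seed=5)
        a = train_eval(X, y, sids, self._plan(sids), cfg)
        b = train_eval(X, y, sids, self._plan(sids), cfg)
        assert np.array_equal(a.confusion.counts, b.confusion.counts)

    def test_single_class_training_set_rejected(self):
        X, y, sids = _separable_images(8)
        plan = SplitPlan(fold=0, train=tuple(s for s in sids if s.startswith("D")),
                         val=("N00",), test=("N01",))
        with pytest.raises(ValueError):
            train_eval(X, y, sids, plan, TrainConfig(seed=0))

    def test_transfer_recipe_matches_published_hyperparameters(self):
        cfg = transfer_recipe()
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.batch_size == 32
        assert cfg.max_epochs == 50
        assert cfg.patience == 10


class TestCompare:
    def _metrics(self, acc):
        counts = np.round(np.array([[acc * 10, (1 - acc) * 10], [0, 10]])).astype(int)
        return metrics_from_confusion(ConfusionMatrix(counts, ("a", "b")))

    def test_identical_folds_give_p_one(self):
        ms = [self._metrics(0.8) for _ in range(5)]
        rep = compare_modalities(ms, ms)
        assert (rep["mean_diff"] == 0).all()
        assert (rep["p"] == 1.0).all()

    def test_constant_offset_detected(self):
        rng = np.random.default_rng(0)
        accs = [0.55, 0.6, 0.65, 0.7, 0.6]
        a = [self._metrics(x + 0.2) for x in accs]
        b = [self._metrics(x) for x in accs]
        rep = compare_modalities(a, b).set_index("metric")
        assert rep.loc["accuracy", "p"] < 0.05
        assert rep.loc["accuracy", "mean_diff"] > 0

    def test_mismatched_fold_counts_rejected(self):
        ms = [self._metrics(0.8)] * 3
        with pytest.raises(ValueError):
            compare_modalities(ms, ms[:2])
        with pytest.raises(ValueError):
            compare_modalities(ms[:1], ms[:1])
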