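import numpy as np
import pytest

import gazedecode as gz
from gazedecode.decoding import _tune_params


def dummy_trial(pid, img, group="A", n=4):
    return gz.Trial(
        participant_id=pid, image_id=img, group=group,
        t_ms=np.arange(n) * (1000 / 60),
        x=np.full(n, 0.5), y=np.full(n, 0.3),
    )


@pytest.fixture(scope="module")
def full_design_keys():
    """71 participants x 14 images as lightweight dummy trials."""
    return [
        dummy_trial(f"P{p:02d}", f"I{i:02d}")
        for p in range(71) for i in range(14)
    ]


class TestMakeFolds:
    def test_leave_one_image_out_full_design(self, full_design_keys):
        plan = gz.make_folds(full_design_keys, "leave_one_image_out")
        assert len(plan) == 14
        for train, val in plan.folds:
            assert len(val) == 71
            assert len(train) == 923  # (14 - 1) x 71
            val_images = {img for _, img in val}
            assert len(val_images) == 1
            assert not any(img in val_images for _, img in train)
            assert not set(train) & set(val)

    def test_repeated_split_sizes(self, full_design_keys):
        plan = gz.make_folds(
            full_design_keys, "repeated_split", n_iter=14, val_fraction=0.3,
            seed=3,
        )
        assert len(plan) == 14
        for train, val in plan.folds:
            assert len(val) == 298  # floor(0.3 * 994)
            assert len(train) == 994 - 298
            assert not set(train) & set(val)

    def test_repeated_split_seeded(self, full_design_keys):
        a = gz.make_folds(full_design_keys, "repeated_split", seed=5)
        b = gz.make_folds(full_design_keys, "repeated_split", seed=5)
        c = gz.make_folds(full_design_keys, "repeated_split", seed=6)
        assert a.folds == b.folds
        assert a.folds != c.folds

    def test_per_image_scheme_one_fold_per_participant(self, full_design_keys):
        plan = gz.make_folds(
            full_design_keys, "leave_one_participant_out_per_image",
            image_id="I00",
        )
        assert len(plan) == 71
        for train, val in plan.folds:
            assert len(val) == 1
            assert len(train) == 70

    def test_incomplete_design_lists_missing_pairs(self, full_design_keys):
        with pytest.raises(ValueError, match="P00.*I00"):
            gz.make_folds(full_design_keys[1:], "leave_one_image_out")


class TestSelectFeatures:
    def test_perfect_feature_always_kept(self, rng):
        """One feature separating the classes among 99 noise features is
        selected under every threshold in the grid."""
        n = 60
        y = np.repeat(["a", "b"], n // 2)
        X = rng.normal(size=(n, 100))
        X[:, 42] = (y == "a") * 2.0 + rng.normal(0, 0.05, n)
        spec = gz.ClassifierSpec(family="linear_svm")
        for t in spec.selection_thresholds:
            one_t = gz.ClassifierSpec(
                family="linear_svm", selection_thresholds=(t,),
                selector_max_depth=(10,), selector_min_samples_split=(2,),
            )
            sel = gz.select_features(X, y, one_t, seed=0)
            assert 42 in sel

    def test_all_constant_features_fall_back_to_one(self):
        X = np.ones((20, 5))
        y = np.repeat(["a", "b"], 10)
        spec = gz.ClassifierSpec(
            family="linear_svm", selection_thresholds=(1.7,),
            selector_max_depth=(10,), selector_min_samples_split=(2,),
        )
        with pytest.warns(UserWarning, match="top-1"):
            sel = gz.select_features(X, y, spec, seed=0)
        assert sel.size == 1

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            gz.select_features(X, np.repeat("a", 10),
                               gz.ClassifierSpec(), seed=0)

    def test_depends_only_on_training_rows(self, rng):
        X = rng.normal(size=(40, 20))
        y = np.tile(["a", "b"], 20)
        X[:, 3] += (y == "a") * 1.5
        spec = gz.ClassifierSpec(
            family="linear_svm", selection_thresholds=(1.8,),
            selector_max_depth=(10,), selector_min_samples_split=(2,),
        )
        s1 = gz.select_features(X, y, spec, seed=1)
        s2 = gz.select_features(X.copy(), y.copy(), spec, seed=1)
        assert np.array_equal(s1, s2)


class TestTestVsChance:
    def test_all_at_chance_gives_p_one(self):
        with pytest.warns(UserWarning):
            stat, p = gz.test_vs_chance(np.full(14, 0.5), 0.5)
        assert (stat, p) == (0.0, 1.0)

    def test_degenerate_above_chance(self):
        with pytest.warns(UserWarning):
            stat, p = gz.test_vs_chance(np.full(14, 0.6), 0.5)
        assert stat == np.inf and p == 0.0

    def test_matches_scipy_t_test(self, rng):
        acc = rng.normal(0.55, 0.05, 14)
        from scipy import stats

        stat, p = gz.test_vs_chance(acc, 0.5)
        ref = stats.ttest_1samp(acc, 0.5)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_type_one_error_rate_near_alpha(self):
        """Null folds ~ Normal(0.5, 0.05), n = 14: rejection rate at
        alpha = 0.05 stays near 0.05 over 2000 replicates."""
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(2000):
            acc = rng.normal(0.5, 0.05, 14)
            _, p = gz.test_vs_chance(acc, 0.5)
            rejections += p < 0.05
        assert rejections / 2000 == pytest.approx(0.05, abs=0.015)

    def test_requires_two_folds(self):
        with pytest.raises(ValueError):
            gz.test_vs_chance(np.array([0.5]), 0.5)


@pytest.fixture(scope="module")
def tiny_decoding_setup():
    """4 well-separated individuals x 6 images, short trials."""
    cohort = gz.make_separated_cohort(2, 2, seed=1, log_mean_spacing=0.6)
    layouts = gz.default_layouts(6, seed=0)
    trials = gz.simulate_dataset(cohort, layouts, duration_s=3.0, seed=5)
    spec = gz.ClassifierSpec(
        family="rbf_svm",
        selector_max_depth=(10,), selector_min_samples_split=(2,),
        selection_thresholds=(1.7, 2.1),
    )
    return trials, spec


class TestRunDecoding:
    def test_identity_recovery_above_chance(self, tiny_decoding_setup):
        trials, spec = tiny_decoding_setup
        folds = gz.make_folds(trials, "leave_one_image_out")
        res = gz.run_decoding(trials, "individual", folds, spec, seed=0)
        assert res.chance == pytest.approx(0.25)
        assert res.mean_accuracy >= 3 * res.chance
        assert len(res.per_fold_accuracy) == 6

    def test_confusion_conserves_counts_and_accuracy(self, tiny_decoding_setup):
        trials, spec = tiny_decoding_setup
        folds = gz.make_folds(trials, "leave_one_image_out")
        res = gz.run_decoding(trials, "individual", folds, spec, seed=0)
        assert res.confusion.sum() == len(trials)
        assert res.pooled_accuracy == pytest.approx(
            np.mean(res.per_fold_accuracy)
        )
        row_sums = res.confusion.sum(axis=1)
        assert np.all(row_sums == 6)  # one validation trial per image

    def test_topk_equal_to_nclasses_is_perfect(self, tiny_decoding_setup):
        trials, spec = tiny_decoding_setup
        folds = gz.make_folds(trials, "leave_one_image_out")
        res = gz.run_decoding(
            trials, "individual", folds, spec, seed=0, top_k=4
        )
        assert res.topk_accuracy == 1.0

    def test_permuted_labels_fall_to_chance(self, tiny_decoding_setup):
        trials, spec = tiny_decoding_setup
        folds = gz.make_folds(trials, "leave_one_image_out")
        rng = np.random.default_rng(0)
        pids = [t.participant_id for t in trials]
        perm = rng.permutation(pids)
        label_map = {t.key: perm[i] for i, t in enumerate(trials)}
        res = gz.run_decoding(
            trials, "individual", folds, spec, seed=0, label_map=label_map
        )
        n = len(trials)
        half_width = 1.96 * np.sqrt(0.25 * 0.75 / n)
        assert abs(res.pooled_accuracy - 0.25) <= half_width

    def test_group_chance_is_half(self, tiny_decoding_setup):
        trials, spec = tiny_decoding_setup
        folds = gz.make_folds(
            trials, "repeated_split", n_iter=3, seed=2
        )
        res = gz.run_decoding(trials, "group", folds, spec, seed=0)
        assert res.chance == 0.5
        assert set(res.classes) == {"A", "B"}


class TestPerImageGroupDecoding:
    def test_disjoint_rois_recover_groups(self):
        cohort = gz.make_cohort(6, 6, seed=3)
        layouts = gz.default_layouts(1, seed=1, disjoint=True)
        trials = gz.simulate_dataset(cohort, layouts, duration_s=3.0, seed=4)
        res = gz.per_image_group_decoding(trials, "img01", grid=20, seed=0)
        assert len(res.per_fold_accuracy) == 12
        assert res.pooled_accuracy >= 0.9
        assert res.confusion.sum() == 12

    def test_missing_participant_listed(self):
        cohort = gz.make_cohort(2, 2, seed=3)
        layouts = gz.default_layouts(2, seed=1)
        trials = gz.simulate_dataset(cohort, layouts, duration_s=2.0, seed=4)
        dropped = [
            t for t in trials
            if not (t.participant_id == "A001" and t.image_id == "img01")
        ]
        with pytest.raises(ValueError, match="A001"):
            gz.per_image_group_decoding(dropped, "img01")


class TestTuneParams:
    def test_grid_of_one_short_circuits(self, rng):
        spec = gz.ClassifierSpec(family="rbf_svm", hyper_grid={"C": [2]})
        X = rng.normal(size=(12, 3))
        y = np.tile(["a", "b"], 6)
        assert _tune_params(X, y, spec, seed=0) == {"C": 2}

    def test_picks_within_grid(self, rng):
        spec = gz.ClassifierSpec(family="rbf_svm")
        X = rng.normal(size=(30, 5))
        y = np.tile(["a", "b"], 15)
        X[:, 0] += (y == "a") * 2
        params = _tune_params(X, y, spec, seed=0)
        assert params["C"] in [0.25, 0.5, 1, 2, 4]
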