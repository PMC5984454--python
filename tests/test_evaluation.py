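"""Information indices, CV harness, baselines, and the full experiment."""

import numpy as np
import pandas as pd
import pytest

from rankcbr.errors import ConfigError, StratificationError
from rankcbr.evaluation import (
    ConfusionCounts,
    calibrate_scucc_threshold,
    confusion_counts,
    information_indices,
    knn_baseline,
    run_experiment,
    scucc_classify,
    scucc_composite,
    stratified_kfold,
    summarize,
)
from rankcbr.simulate import generate_cohort

from conftest import make_case, separable_spec


class TestInformationIndices:
    @pytest.mark.parametrize(
        "cc, precision, recall, f1, g",
        [
            # cross-checked against a published 14-case fold report
            (ConfusionCounts(tp=5, fp=5, fn=2, tn=2), 0.5000, 0.7143, 0.5882, 0.5976),
            (ConfusionCounts(tp=2, fp=0, fn=5, tn=7), 1.0000, 0.2857, 0.4444, 0.5345),
            (ConfusionCounts(tp=7, fp=0, fn=0, tn=7), 1.0000, 1.0000, 1.0000, 1.0000),
        ],
    )
    def test_known_values(self, cc, precision, recall, f1, g):
        idx = information_indices(cc)
        assert idx["precision"] == pytest.approx(precision, abs=1e-4)
        assert idx["recall"] == pytest.approx(recall, abs=1e-4)
        assert idx["f1"] == pytest.approx(f1, abs=1e-4)
        assert idx["g"] == pytest.approx(g, abs=1e-4)

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning, match="zero denominator"):
            idx = information_indices(ConfusionCounts(tp=0, fp=0, fn=3, tn=4))
        assert idx["precision"] == 0.0 and idx["f1"] == 0.0

    def test_means_ordering(self, rng):
        """F1 (harmonic) <= G (geometric) <= arithmetic mean of P and R,
        with equality when P == R."""
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 20, size=4)
            idx = information_indices(ConfusionCounts(int(tp), int(fp),
                                                      int(fn), int(tn)))
            p, r = idx["precision"], idx["recall"]
            assert idx["f1"] <= idx["g"] + 1e-12
            assert idx["g"] <= (p + r) / 2 + 1e-12
            assert min(p, r) - 1e-12 <= idx["f1"] <= max(p, r) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=1)

    def test_confusion_counts_total(self, rng):
        y = rng.integers(0, 2, 20)
        p = rng.integers(0, 2, 20)
        cc = confusion_counts(y, p)
        assert cc.tp + cc.fp + cc.fn + cc.tn == 20


class TestSummarize:
    def test_published_per_fold_column_average(self):
        """Per-fold precisions (1, 1, .7778, 1, .7778) average to 0.9111."""
        df = pd.DataFrame(
            {"model": "M", "precision": [1.0, 1.0, 0.7778, 1.0, 0.7778],
             "recall": 1.0, "f1": 1.0, "g": 1.0}
        )
        out = summarize(df).set_index("index")
        assert out.loc["precision", "AVG"] == pytest.approx(0.9111, abs=1e-4)

    def test_sample_std_convention(self):
        """STD uses the n-1 denominator: the published F-1 column
        (.8333, .9231, .8750, 1.0, .8750) has sample SD 0.0637."""
        df = pd.DataFrame(
            {"model": "M", "precision": 1.0, "recall": 1.0,
             "f1": [0.8333, 0.9231, 0.8750, 1.0000, 0.8750], "g": 1.0}
        )
        out = summarize(df).set_index("index")
        assert out.loc["f1", "STD"] == pytest.approx(0.0637, abs=1e-4)

    def test_constant_column(self):
        df = pd.DataFrame(
            {"model": "M", "precision": [0.5] * 3, "recall": [0.5] * 3,
             "f1": [0.5] * 3, "g": [0.5] * 3}
        )
        out = summarize(df)
        assert (out["STD"] == 0).all()
        assert (out["MIN"] == out["MAX"]).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())


class TestStratifiedKFold:
    def test_balanced_70_case_partition(self):
        labels = ["cancer"] * 35 + ["control"] * 35
        folds = stratified_kfold(labels, k_folds=5, seed=1)
        y = np.array([1] * 35 + [0] * 35)
        all_test = []
        for train_idx, test_idx in folds:
            assert len(test_idx) == 14 and len(train_idx) == 56
            assert y[test_idx].sum() == 7  # 7 cancer + 7 control per fold
            all_test.extend(test_idx.tolist())
        assert sorted(all_test) == list(range(70))

    def test_seed_reproducible(self):
        labels = [0, 1] * 10
        a = stratified_kfold(labels, 5, seed=9)
        b = stratified_kfold(labels, 5, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert np.array_equal(te1, te2)

    def test_too_many_folds_rejected(self):
        with pytest.raises(StratificationError):
            stratified_kfold([0, 0, 0, 1, 1], k_folds=3, seed=0)


class TestKnnBaseline:
    def test_exact_match_wins_k1(self, rng):
        train = [make_case(rng) for _ in range(6)]
        y = np.array([0, 1, 0, 1, 0, 1])
        pred, prob = knn_baseline(train, y, [train[3]], k=1)
        assert pred[0] == 1 and prob[0] == 1.0

    def test_vote_probability(self, rng):
        from dataclasses import replace

        target = make_case(rng)
        train = [replace(target, t1=target.t1 + eps)
                 for eps in (0.1, 0.2, 0.3, 0.4, 0.5, 9.0)]
        y = np.array([0, 0, 0, 0, 1, 1])
        pred, prob = knn_baseline(train, y, [target], k=5)
        assert pred[0] == 0
        assert prob[0] == pytest.approx(0.2)

    def test_perfect_on_separable_cohort(self):
        from rankcbr.profiles import extract_features

        curves, labels = generate_cohort(separable_spec(n_subjects=20,
                                                        grid_length=151))
        cases = [extract_features(c) for c in curves]
        y = np.array([1 if l == "cancer" else 0 for l in labels])
        pred, _ = knn_baseline(cases[:16], y[:16], cases[16:], k=5)
        assert np.array_equal(pred, y[16:])


class TestSCUCC:
    def test_reference_mean_is_control(self, rng):
        ref = rng.normal(0.5, 0.1, size=(10, 40)) + np.sin(
            np.linspace(0, 3, 40))
        target = ref.mean(axis=0)
        c = scucc_composite(ref, target)
        assert c > 0.5  # high correlation and central band position
        _, label = scucc_classify(ref, target, threshold=0.2)
        assert label == "control"

    def test_negated_shape_is_cancer(self, rng):
        base = np.sin(np.linspace(0, 3, 40))
        ref = base + rng.normal(0, 0.05, size=(10, 40))
        c, label = scucc_classify(ref, -base, threshold=0.0)
        assert c <= 0
        assert label == "cancer"

    def test_degenerate_points_skipped_with_warning(self):
        ref = np.tile(np.linspace(0, 1, 20), (3, 1))
        ref[:, 10:] += np.array([[0.0], [0.1], [0.2]])  # first half constant
        with pytest.warns(RuntimeWarning, match="zero reference sd"):
            scucc_composite(ref, ref.mean(axis=0))

    def test_threshold_calibration_separates_training_set(self, rng):
        curves, labels = generate_cohort(separable_spec(n_subjects=12,
                                                        grid_length=101))
        X = np.vstack([c.dcp for c in curves])
        y = np.array([1 if l == "cancer" else 0 for l in labels])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            thr = calibrate_scucc_threshold(X, y)
            comps = np.array([scucc_composite(X[y == 0], row) for row in X])
        pred = (comps < thr).astype(int)
        assert np.array_equal(pred, y)


class TestRunExperiment:
    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigError, match="SVM"):
            run_experiment({"models": ["SVM"], "seed": 0})

    def test_retain_disabled_with_warning(self, tiny_cohort):
        _, _, spec = tiny_cohort
        cfg = {"cohort": spec, "models": ["CLCBR"], "seed": 1, "k_folds": 2}
        base = run_experiment(cfg)
        with pytest.warns(RuntimeWarning, match="retain is disabled"):
            retained = run_experiment({**cfg, "retain": True})
        pd.testing.assert_frame_equal(base.folds, retained.folds)

    def test_deterministic_rerun_byte_identical(self, tiny_cohort):
        _, _, spec = tiny_cohort
        cfg = {"cohort": spec, "models": ["CLCBR", "RWCBR"], "seed": 5,
               "k_folds": 2}
        a = run_experiment(cfg)
        b = run_experiment(cfg)
        assert a.weights.to_csv() == b.weights.to_csv()
        assert a.folds.to_csv() == b.folds.to_csv()
        assert a.summary.to_csv() == b.summary.to_csv()

    def test_weights_touch_training_folds_only(self, tiny_cohort, monkeypatch):
        """Leakage guard: every weight-estimation call sees exactly the
        training-fold case count."""
        import rankcbr.evaluation as ev

        _, _, spec = tiny_cohort
        seen = []
        orig = ev._WEIGHT_SCHEMES["RWCBR"]

        def spy(cases, labels):
            seen.append(len(cases))
            return orig(cases, labels)

        monkeypatch.setitem(ev._WEIGHT_SCHEMES, "RWCBR", spy)
        run_experiment({"cohort": spec, "models": ["RWCBR"], "seed": 2,
                        "k_folds": 2})
        assert seen == [10, 10]  # 20 subjects, 2 folds -> 10 train each

    def test_output_shapes(self, tiny_cohort):
        _, _, spec = tiny_cohort
        res = run_experiment({"cohort": spec, "seed": 3, "k_folds": 2})
        assert set(res.folds.model) == {"KNN", "SCUCC", "CLCBR", "ETCBR",
                                        "LWCBR", "RWCBR"}
        assert len(res.folds) == 12  # 6 models x 2 folds
        assert len(res.weights) == 8  # 4 weighted schemes x 2 folds
        assert {"MIN", "AVG", "STD", "MAX"} <= set(res.summary.columns)
        # weight rows respect the constraints
        feat_cols = ["IR", "T1", "T2", "PEAK1", "PEAK2", "IND"]
        sums = res.weights[feat_cols].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
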