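"""Metric formulas, cross-validation behaviour and the experiment grid."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

import henactivity as ha


def brute_force_metrics(cm):
    """One-vs-rest tally done the long way, per class."""
    cm = np.asarray(cm, float)
    k = cm.shape[0]
    total = cm.sum()
    precision, recall, f1 = [], [], []
    for i in range(k):
        tp = cm[i, i]
        fp = sum(cm[j, i] for j in range(k) if j != i)
        fn = sum(cm[i, j] for j in range(k) if j != i)
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(f)
    acc = sum(cm[i, i] for i in range(k)) / total
    return acc, precision, recall, f1, float(np.mean(f1))


def _blob_features(n_per_class=40, spread=0.05, seed=0):
    """Three well-separated Gaussian blobs in feature space."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for cls, center in zip((1, 2, 3), ([0, 0], [5, 0], [0, 5])):
        rows.append(rng.normal(center, spread, (n_per_class, 2)))
        labels += [cls] * n_per_class
    df = pd.DataFrame(np.vstack(rows), columns=["f1", "f2"])
    df["label"] = labels
    return df.sample(frac=1.0, random_state=1).reset_index(drop=True)


class TestMetricsFromConfusion:
    def test_perfect_diagonal(self):
        m = ha.metrics_from_confusion(np.diag([5, 5, 5]))
        assert m["accuracy"] == 1.0
        assert np.all(m["f1"] == 1.0)
        assert m["overall_f1"] == 1.0

    def test_precision_from_tp_fp(self):
        # class 1: TP=8, FP=2 (two class-2 windows predicted as 1)
        cm = np.array([[8, 0], [2, 10]])
        m = ha.metrics_from_confusion(cm)
        assert m["precision"][0] == pytest.approx(0.8)

    def test_hand_evaluated_three_class_matrix(self):
        cm = np.array([[10, 0, 0], [0, 5, 5], [0, 0, 10]])
        m = ha.metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(25 / 30)
        assert m["recall"][1] == pytest.approx(0.5)
        assert m["precision"][2] == pytest.approx(10 / 15)
        assert m["recall"][0] == 1.0
        assert m["f1"][1] == pytest.approx(2 * 1.0 * 0.5 / 1.5)
        f1_3 = 2 * (10 / 15) * 1.0 / (10 / 15 + 1.0)
        assert m["f1"][2] == pytest.approx(f1_3)
        assert m["overall_f1"] == pytest.approx(np.mean(m["f1"]))

    def test_zero_denominators_score_zero(self):
        # class 2 never predicted and never true
        cm = np.array([[5, 0], [0, 0]])
        m = ha.metrics_from_confusion(cm)
        assert m["precision"][1] == 0.0
        assert m["f1"][1] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ha.metrics_from_confusion(np.zeros((3, 3)))

    @settings(deadline=None, max_examples=300)
    @given(
        arrays(
            np.int64,
            (3, 3),
            elements=st.integers(min_value=0, max_value=200),
        ).filter(lambda cm: cm.sum() > 0)
    )
    def test_agreement_with_brute_force_tally(self, cm):
        m = ha.metrics_from_confusion(cm)
        acc, precision, recall, f1, overall = brute_force_metrics(cm)
        assert m["accuracy"] == pytest.approx(acc)
        np.testing.assert_allclose(m["precision"], precision)
        np.testing.assert_allclose(m["recall"], recall)
        np.testing.assert_allclose(m["f1"], f1)
        assert m["overall_f1"] == pytest.approx(overall)

    @settings(deadline=None, max_examples=200)
    @given(
        arrays(
            np.int64,
            (3, 3),
            elements=st.integers(min_value=0, max_value=100),
        ).filter(lambda cm: cm.sum() > 0 and (cm.sum(axis=1) > 0).all())
    )
    def test_accuracy_is_recall_weighted_by_class_prevalence(self, cm):
        m = ha.metrics_from_confusion(cm)
        weights = cm.sum(axis=1) / cm.sum()
        assert m["accuracy"] == pytest.approx(float(weights @ m["recall"]))

    def test_macro_f1_invariant_to_relabelling(self):
        rng = np.random.default_rng(8)
        cm = rng.integers(0, 50, (3, 3))
        perm = [2, 0, 1]
        permuted = cm[np.ix_(perm, perm)]
        a = ha.metrics_from_confusion(cm)
        b = ha.metrics_from_confusion(permuted)
        assert a["overall_f1"] == pytest.approx(b["overall_f1"])


class TestCrossval:
    def test_separable_blobs_score_perfectly(self):
        fm = _blob_features()
        rep = ha.crossval(fm, ha.ModelSpec("bagged_trees", 25, 0), seed=0)
        assert rep.accuracy == 1.0
        assert rep.overall_f1 == 1.0
        assert rep.confusion.sum() == len(fm)

    def test_permuted_labels_fall_to_chance(self):
        """With labels shuffled, penalty-free accuracy sits at the
        majority-class proportion (binomial 3-SD band)."""
        rng = np.random.default_rng(9)
        n = 600
        fm = pd.DataFrame(rng.normal(0, 1, (n, 5)), columns=[f"f{i}" for i in range(5)])
        fm["label"] = rng.choice([1, 2], size=n, p=[0.8, 0.2])
        rep = ha.crossval(
            fm, ha.ModelSpec("bagged_trees", 50, 0), penalty=None, seed=0
        )
        p = float((fm["label"] == 1).mean())
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(rep.accuracy - p) < 3 * sd

    def test_fixed_seed_is_bit_reproducible(self):
        fm = _blob_features(spread=1.5, seed=2)
        a = ha.crossval(fm, ha.ModelSpec("random_forest", 20, 3), seed=5)
        b = ha.crossval(fm, ha.ModelSpec("random_forest", 20, 3), seed=5)
        np.testing.assert_array_equal(a.confusion, b.confusion)
        assert a.fold_accuracies == b.fold_accuracies
        assert a.fingerprint == b.fingerprint

    def test_class_with_too_few_windows_rejected(self):
        fm = _blob_features(n_per_class=10)
        fm = pd.concat([fm[fm["label"] != 3], fm[fm["label"] == 3].head(2)])
        with pytest.raises(ValueError, match="fewer than"):
            ha.crossval(fm, ha.ModelSpec("bagged_trees", 10, 0), k=4)

    def test_paper_mode_fits_preprocessing_globally(self):
        from henactivity import preprocess

        fm = _blob_features(spread=1.0, seed=3)
        preprocess.FIT_LOG.clear()
        ha.crossval(
            fm, ha.ModelSpec("random_forest", 10, 0), paper_mode=True, seed=0
        )
        assert preprocess.FIT_LOG == [("standardizer", len(fm))]


class TestHoldout:
    def test_resubstitution_bounds_out_of_fold(self):
        fm = _blob_features(spread=1.8, seed=4)
        model = ha.ModelSpec("bagged_trees", 25, 0)
        resub = ha.holdout_validate(fm, fm, model, seed=0)
        oof = ha.crossval(fm, model, seed=0)
        assert resub.accuracy >= oof.accuracy

    def test_missing_class_warns_not_crashes(self):
        fm = _blob_features(seed=5)
        test = fm[fm["label"] != 3].reset_index(drop=True)
        with pytest.warns(UserWarning, match="absent"):
            rep = ha.holdout_validate(
                fm, test, ha.ModelSpec("bagged_trees", 10, 0), seed=0
            )
        assert rep.recall[3] == 0.0
        assert rep.f1[3] == 0.0

    def test_schema_mismatch_rejected(self):
        fm = _blob_features()
        other = fm.rename(columns={"f1": "g1"})
        with pytest.raises(ValueError, match="schema"):
            ha.holdout_validate(fm, other, ha.ModelSpec("bagged_trees", 5, 0))


class TestPairedTtest:
    def test_identical_inputs_give_p_one(self):
        t, p = ha.paired_ttest([0.8, 0.9, 0.85], [0.8, 0.9, 0.85])
        assert p == 1.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.8, 0.05, 10)
        b = a + 0.03 + rng.normal(0, 0.02, 10)
        t, p = ha.paired_ttest(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-6)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            ha.paired_ttest([0.5], [0.6])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ha.paired_ttest([0.5, 0.6], [0.6])


class TestExperimentGrid:
    def test_single_cell_grid_has_no_tests(self):
        fm = _blob_features(spread=1.0)
        grid = ha.run_experiment_grid(
            {1.0: fm}, pca_options=(False,), repeats=1, n_trees=10, seed=0
        )
        assert len(grid.cells) == 1
        assert grid.comparisons == []

    def test_grid_is_deterministic(self):
        fm = _blob_features(spread=1.5, seed=6)
        kwargs = dict(pca_options=(False, True), repeats=2, n_trees=10, seed=1)
        a = ha.run_experiment_grid({1.0: fm}, **kwargs)
        b = ha.run_experiment_grid({1.0: fm}, **kwargs)
        for key in a.cells:
            for ra, rb in zip(a.cells[key], b.cells[key]):
                np.testing.assert_array_equal(ra.confusion, rb.confusion)
        assert a.comparisons == b.comparisons

    def test_matched_cells_are_compared(self):
        fm = _blob_features(spread=1.5, seed=7)
        grid = ha.run_experiment_grid(
            {1.0: fm, 4.0: fm},
            pca_options=(False, True),
            repeats=2,
            n_trees=10,
            seed=0,
        )
        kinds = {c["kind"] for c in grid.comparisons}
        assert kinds == {"pca_vs_none", "window_vs_window"}
        for comp in grid.comparisons:
            assert 0.0 <= comp["p"] <= 1.0


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ha.ModelSpec("boosted_stumps")
    with pytest.raises(ValueError):
        ha.ModelSpec("bagged_trees", 0)
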