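import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from precision_pathways import (
    RunConfig,
    apply_ensemble,
    compute_confidence,
    fit_dlda,
    patient_accuracy,
    predict_dlda,
    run_repeated_cv,
    select_features_ttest,
    train_full_ensemble,
    tune_feature_count,
)
from conftest import gaussian_assay


class TestSelectFeaturesTtest:
    def test_planted_feature_found_and_matches_scipy_ranking(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 10))
        y = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        X[:10, 4] -= 2.5
        X[10:, 4] += 2.5
        matrix = pd.DataFrame(X, columns=[f"f{j}" for j in range(10)])
        assert select_features_ttest(matrix, y, 1) == ["f4"]
        # full ranking agrees with scipy's Welch t statistics
        t_scipy = np.abs(stats.ttest_ind(X[y == "a"], X[y == "b"], equal_var=False).statistic)
        top3 = set(matrix.columns[np.argsort(-t_scipy)[:3]])
        assert set(select_features_ttest(matrix, y, 3)) == top3

    def test_count_clipped_to_feature_number(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.normal(size=(10, 10)), columns=[f"f{j}" for j in range(10)])
        y = np.array(["a", "b"] * 5, dtype=object)
        assert len(select_features_ttest(matrix, y, 100)) == 10

    def test_tied_features_break_by_column_order(self):
        base = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        matrix = pd.DataFrame({"dup_b": base, "dup_a": base})
        y = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        assert select_features_ttest(matrix, y, 1) == ["dup_b"]

    def test_small_class_errors(self):
        matrix = pd.DataFrame({"f0": [0.0, 1.0, 2.0]})
        y = np.array(["a", "b", "b"], dtype=object)
        with pytest.raises(ValueError, match=">= 2 samples"):
            select_features_ttest(matrix, y, 1)


class TestTuneFeatureCount:
    def test_single_candidate_short_circuits(self):
        matrix = pd.DataFrame(np.random.default_rng(0).normal(size=(8, 40)))
        matrix.columns = [f"f{j}" for j in range(40)]
        y = np.array(["a", "b"] * 4, dtype=object)
        assert tune_feature_count(matrix, y, [30]) == 30

    def test_sparse_signal_prefers_small_count(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 100))
        y = np.array(["a", "b"] * 30, dtype=object)
        X[y == "b", :10] += 3.0
        matrix = pd.DataFrame(X, columns=[f"f{j}" for j in range(100)])
        chosen = tune_feature_count(matrix, y, [10, 100], rng=np.random.default_rng(1))
        assert chosen == 10

    def test_pure_noise_ties_resolve_to_smallest(self):
        # with no signal, inner scores hover at chance; on exact ties the
        # smaller candidate must win.  Perfectly tied scores are forced by
        # duplicated candidates after clipping.
        matrix = pd.DataFrame(np.random.default_rng(5).normal(size=(12, 6)),
                              columns=[f"f{j}" for j in range(6)])
        y = np.array(["a", "b"] * 6, dtype=object)
        assert tune_feature_count(matrix, y, [10, 20, 30], rng=np.random.default_rng(2)) == 6


class TestDLDA:
    def test_parameters_match_direct_formulas(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 2))
        y = np.array(["a"] * 12 + ["b"] * 18, dtype=object)
        model = fit_dlda(pd.DataFrame(X, columns=["u", "v"]), y)
        np.testing.assert_allclose(model.means[0], X[:12].mean(axis=0))
        np.testing.assert_allclose(model.means[1], X[12:].mean(axis=0))
        pooled = (
            ((X[:12] - X[:12].mean(axis=0)) ** 2).sum(axis=0)
            + ((X[12:] - X[12:].mean(axis=0)) ** 2).sum(axis=0)
        ) / (30 - 2)
        np.testing.assert_allclose(model.variances, pooled)
        np.testing.assert_allclose(model.priors, [12 / 30, 18 / 30])

    def test_duplicating_samples_preserves_means_and_variance_scale(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("xyz"))
        y = np.array(["a", "b"] * 5, dtype=object)
        m1 = fit_dlda(X, y)
        m2 = fit_dlda(pd.concat([X, X], ignore_index=True), np.concatenate([y, y]))
        np.testing.assert_allclose(m1.means, m2.means)
        np.testing.assert_allclose(m1.priors, m2.priors)
        # pooled variance differs only through the dof correction
        np.testing.assert_allclose(m2.variances * (20 - 2) / 20, m1.variances * (10 - 2) / 10)

    def test_separated_one_dim_classes(self):
        X = pd.DataFrame({"f": [0.0, 0.0, 10.0, 10.0]})
        y = np.array(["a", "a", "b", "b"], dtype=object)
        model = fit_dlda(X, y)
        np.testing.assert_allclose(model.means.ravel(), [0.0, 10.0])
        np.testing.assert_allclose(model.priors, [0.5, 0.5])
        assert model.variances[0] > 0  # floored
        pred = predict_dlda(model, pd.DataFrame({"f": [-1.0, 11.0]}))
        assert pred.tolist() == ["a", "b"]

    def test_midpoint_tie_goes_to_first_listed_class(self):
        X = pd.DataFrame({"f": [0.0, 1.0, 3.0, 4.0]})
        y = np.array(["a", "a", "b", "b"], dtype=object)
        model = fit_dlda(X, y)
        assert predict_dlda(model, pd.DataFrame({"f": [2.0]}))[0] == "a"

    def test_predictions_match_brute_force_density_oracle(self):
        rng = np.random.default_rng(21)
        Xtr = rng.normal(size=(40, 5))
        ytr = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        Xtr[:20] -= 0.8
        cols = [f"f{j}" for j in range(5)]
        model = fit_dlda(pd.DataFrame(Xtr, columns=cols), ytr)
        Xte = pd.DataFrame(rng.normal(size=(50, 5)), columns=cols)
        # oracle: full log normal density per feature + log prior
        dens = []
        for i, c in enumerate(model.classes):
            logpdf = stats.norm.logpdf(
                Xte.to_numpy(), loc=model.means[i], scale=np.sqrt(model.variances)
            ).sum(axis=1)
            dens.append(np.log(model.priors[i]) + logpdf)
        oracle = np.asarray(model.classes, dtype=object)[np.argmax(np.vstack(dens), axis=0)]
        np.testing.assert_array_equal(predict_dlda(model, Xte), oracle)

    def test_missing_feature_errors(self):
        X = pd.DataFrame({"f": [0.0, 1.0, 3.0, 4.0]})
        y = np.array(["a", "a", "b", "b"], dtype=object)
        model = fit_dlda(X, y)
        with pytest.raises(KeyError, match="f"):
            predict_dlda(model, pd.DataFrame({"g": [1.0]}))


class TestConfidence:
    @pytest.mark.parametrize(
        "votes, expected",
        [
            (["a"] * 50, 1.0),
            (["a"] * 25 + ["b"] * 25, 0.0),
            (["a"] * 40 + ["b"] * 10, 0.6),
            (["a"] * 30 + ["b"] * 20, 0.2),
        ],
    )
    def test_formula_cases(self, votes, expected):
        _, conf = compute_confidence(votes, np.random.default_rng(0))
        assert conf == pytest.approx(expected)

    def test_exact_tie_class_drawn_from_seeded_stream(self):
        votes = ["a", "b"] * 10
        picks = {
            compute_confidence(votes, np.random.default_rng(seed))[0]
            for seed in range(20)
        }
        assert picks == {"a", "b"}  # both reachable
        # same seed -> same pick
        a = compute_confidence(votes, np.random.default_rng(3))[0]
        b = compute_confidence(votes, np.random.default_rng(3))[0]
        assert a == b

    @given(st.lists(st.sampled_from(["a", "b"]), min_size=1, max_size=60),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_to_vote_order_and_relabeling(self, votes, seed):
        rng = lambda: np.random.default_rng(seed)
        _, conf = compute_confidence(votes, rng())
        _, conf_shuffled = compute_confidence(list(reversed(votes)), rng())
        swapped = [{"a": "b", "b": "a"}[v] for v in votes]
        _, conf_swapped = compute_confidence(swapped, rng())
        assert conf == pytest.approx(conf_shuffled)
        assert conf == pytest.approx(conf_swapped)
        assert 0.0 <= conf <= 1.0

    @given(st.integers(1, 60), st.integers(0, 60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_confidence_granularity(self, r, m):
        """With r votes the confidence lies on the grid {2|m/r - 0.5|}."""
        m = min(m, r)
        votes = ["a"] * m + ["b"] * (r - m)
        _, conf = compute_confidence(votes, np.random.default_rng(0))
        grid = {2 * abs(k / r - 0.5) for k in range(r + 1)}
        assert any(conf == pytest.approx(g) for g in grid)

    @pytest.mark.parametrize(
        "votes, truth, expected",
        [(["a"] * 10, "a", 1.0), (["a"] * 30 + ["b"] * 20, "a", 0.6), (["b"] * 5, "a", 0.0)],
    )
    def test_patient_accuracy(self, votes, truth, expected):
        assert patient_accuracy(votes, truth) == pytest.approx(expected)


class TestRepeatedCV:
    def test_every_patient_gets_exactly_r_votes(self):
        assay, labels = gaussian_assay("p", n_per_class=4, n_features=6, delta=1.0, seed=1)
        cfg = RunConfig(repeats=3, feature_counts=(3,), seed=2)
        preds = run_repeated_cv(assay, labels, cfg)
        assert preds.votes.shape == (8, 3)
        assert not preds.votes.isna().any().any()

    def test_perfect_separation_gives_unit_confidence(self):
        assay, labels = gaussian_assay("p", n_per_class=15, n_features=10, delta=20.0, seed=3)
        cfg = RunConfig(repeats=10, feature_counts=(2,), seed=4)
        preds = run_repeated_cv(assay, labels, cfg)
        assert (preds.confidence == 1.0).all()
        assert (preds.majority == labels).all()

    def test_same_seed_reproduces_votes_exactly(self):
        assay, labels = gaussian_assay("p", n_per_class=8, n_features=8, delta=2.0, seed=5)
        cfg = RunConfig(repeats=4, feature_counts=(3, 5), seed=9)
        a = run_repeated_cv(assay, labels, cfg)
        b = run_repeated_cv(assay, labels, cfg)
        pd.testing.assert_frame_equal(a.votes, b.votes)
        c = run_repeated_cv(assay, labels, RunConfig(repeats=4, feature_counts=(3, 5), seed=10))
        assert c.votes.shape == a.votes.shape

    def test_permuted_labels_give_chance_level_accuracy(self):
        assay, labels = gaussian_assay("p", n_per_class=15, n_features=10, delta=6.0, seed=6)
        permuted = pd.Series(
            np.random.default_rng(0).permutation(labels.values), index=labels.index
        )
        cfg = RunConfig(repeats=20, feature_counts=(3,), seed=11)
        preds = run_repeated_cv(assay, permuted, cfg)
        mean_acc = preds.accuracy(permuted).mean()
        assert 0.3 < mean_acc < 0.7

    def test_class_smaller_than_fold_count_errors(self):
        assay, labels = gaussian_assay("p", n_per_class=3, n_features=4, delta=1.0, seed=7)
        labels.iloc[:] = ["a"] * 5 + ["b"]
        with pytest.raises(ValueError, match="stratify"):
            run_repeated_cv(assay, labels, RunConfig(folds=2, repeats=2, feature_counts=(2,)))


class TestFrozenEnsemble:
    def test_model_count_is_repeats_times_folds(self):
        assay, labels = gaussian_assay("p", n_per_class=6, n_features=6, delta=3.0, seed=8)
        ens = train_full_ensemble(assay, labels, RunConfig(repeats=3, feature_counts=(3,), seed=1))
        assert ens.n_models == 3 * 2
        ens1 = train_full_ensemble(assay, labels, RunConfig(repeats=1, feature_counts=(3,), seed=1))
        assert ens1.n_models == 2

    def test_self_application_matches_cv_majority(self):
        assay, labels = gaussian_assay("p", n_per_class=12, n_features=8, delta=8.0, seed=9)
        cfg = RunConfig(repeats=5, feature_counts=(3,), seed=13)
        cv = run_repeated_cv(assay, labels, cfg)
        ens = train_full_ensemble(assay, labels, cfg)
        applied = apply_ensemble(ens, assay)
        assert applied.votes.shape[1] == 10
        # strong separation: majority classes agree between the two modes
        assert (applied.majority == cv.majority).all()

    def test_single_external_patient_gets_all_votes(self):
        assay, labels = gaussian_assay("p", n_per_class=8, n_features=6, delta=5.0, seed=10)
        cfg = RunConfig(repeats=5, feature_counts=(3,), seed=3)
        ens = train_full_ensemble(assay, labels, cfg)
        one = type(assay)(name="p", matrix=assay.matrix.iloc[:1], cost=assay.cost)
        applied = apply_ensemble(ens, one)
        assert applied.votes.shape == (1, 10)

    def test_missing_feature_named_in_error(self):
        assay, labels = gaussian_assay("p", n_per_class=8, n_features=6, delta=5.0, seed=10)
        cfg = RunConfig(repeats=2, feature_counts=(6,), seed=3)
        ens = train_full_ensemble(assay, labels, cfg)
        crippled = type(assay)(
            name="p", matrix=assay.matrix.drop(columns=["p_f0"]), cost=assay.cost
        )
        with pytest.raises(KeyError, match="p_f0"):
            apply_ensemble(ens, crippled)
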