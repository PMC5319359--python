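"""Flexible discriminant analysis, pFDA, CV, Wilks power, structure."""

import numpy as np
import pandas as pd
import pytest

import ecomorph as em

from conftest import star_newick


def two_class_data(n=60, sep=10.0, p=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    labels = np.repeat(["a", "b"], n // 2)
    X[labels == "b", 0] += sep
    return pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                        columns=[f"v{j}" for j in range(p)]), pd.Series(
        labels, index=[f"s{i}" for i in range(n)])


class TestFDA:
    def test_strong_separation_classifies_training_perfectly(self):
        X, labels = two_class_data()
        model = em.fda_fit(X, labels)
        assert (model.predict(X) == labels).all()

    def test_percent_between_sums_to_100(self, diet_training):
        X, labels = diet_training
        model = em.fda_fit(X, labels)
        assert model.percent_between.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(model.eigenvalues) <= 1e-9).all()
        assert model.n_functions <= len(model.classes) - 1

    def test_shuffled_labels_keep_invariants(self, diet_training):
        X, labels = diet_training
        shuffled = pd.Series(
            np.random.default_rng(1).permutation(labels.to_numpy()),
            index=labels.index)
        model = em.fda_fit(X, shuffled)
        assert model.percent_between.sum() == pytest.approx(100.0, abs=1e-6)

    def test_two_class_direction_matches_lda_closed_form(self):
        """FDA coefficients align with Sigma^-1 (mu_b - mu_a)."""
        X, labels = two_class_data(n=200, sep=2.0, p=4, seed=3)
        model = em.fda_fit(X, labels)
        Xa = X[labels == "a"].to_numpy()
        Xb = X[labels == "b"].to_numpy()
        S = (np.cov(Xa.T) * (len(Xa) - 1)
             + np.cov(Xb.T) * (len(Xb) - 1)) / (len(X) - 2)
        direction = np.linalg.solve(S, Xb.mean(0) - Xa.mean(0))
        w = model.coefficients.to_numpy()[:, 0]
        cos = abs(w @ direction) / (np.linalg.norm(w) * np.linalg.norm(direction))
        assert cos >= 1 - 1e-6

    def test_scores_match_sklearn_lda(self, diet_training):
        """Cross-check: DF1 correlates with scikit-learn's first LD axis."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, labels = diet_training
        model = em.fda_fit(X, labels)
        lda = sklearn.LinearDiscriminantAnalysis(n_components=1)
        z = lda.fit_transform(X.to_numpy(), labels.to_numpy())[:, 0]
        r = abs(np.corrcoef(model.scores["DF1"], z)[0, 1])
        assert r > 0.999

    def test_unknown_labels_rejected(self, diet_training):
        X, labels = diet_training
        bad = labels.copy()
        bad.iloc[0] = "U"
        with pytest.raises(ValueError, match="unknown"):
            em.fda_fit(X, bad)


class TestPrediction:
    def test_point_at_centroid_recovers_class(self, diet_training):
        X, labels = diet_training
        model = em.fda_fit(X, labels)
        # invert the score map at the class centroid via least squares
        coef = model.coefficients.to_numpy()
        target = model.class_centroids.loc["GH"].to_numpy() - model.const
        x0 = model.x_mean.to_numpy() + np.linalg.lstsq(
            coef.T, target, rcond=None)[0]
        pred = model.predict(pd.DataFrame([x0], columns=X.columns))
        assert pred.iloc[0] == "GH"

    def test_equidistant_tie_breaks_lexicographically(self):
        """Exactly symmetric classes: the midpoint goes to the earlier code."""
        X = pd.DataFrame({"v": [-2.0, -1.0, 1.0, 2.0]},
                         index=list("wxyz"))
        labels = pd.Series(["I", "I", "C", "C"], index=list("wxyz"))
        model = em.fda_fit(X, labels)
        pred = model.predict(pd.DataFrame({"v": [0.0]}))
        assert pred.iloc[0] == "C"

    def test_column_mismatch_raises(self, diet_training):
        X, labels = diet_training
        model = em.fda_fit(X, labels)
        with pytest.raises(ValueError, match="columns"):
            model.predict(X.iloc[:, :5])

    def test_held_out_strong_shifts_recovered(self):
        X, labels = two_class_data(n=100, sep=8.0, seed=4)
        Xtest, ytest = two_class_data(n=100, sep=8.0, seed=5)
        model = em.fda_fit(X, labels)
        assert (model.predict(Xtest) == ytest).mean() >= 0.95


class TestCrossValidation:
    def test_separable_data_perfect(self):
        X, labels = two_class_data(n=80, sep=10.0)
        cv = em.cross_validate(X, labels, n_partitions=10, seed=0)
        assert cv.overall_correct == 1.0
        assert cv.n_partitions == 10

    def test_confusion_rows_sum_to_class_sizes(self, diet_training):
        X, labels = diet_training
        with pytest.warns(RuntimeWarning, match="folds"):
            cv = em.cross_validate(X, labels, n_partitions=len(X), seed=1)
        counts = labels.value_counts()
        for c in cv.confusion.index:
            assert cv.confusion.loc[c].sum() == counts[c]

    def test_permuted_labels_near_chance(self):
        X, labels = two_class_data(n=120, sep=0.0, seed=6)
        cv = em.cross_validate(X, labels, n_partitions=10, seed=2)
        # max class frequency 0.5; binomial 4-sigma band at n=120
        assert abs(cv.overall_correct - 0.5) < 4 * np.sqrt(0.25 / 120)

    def test_reproducible_given_seed(self, diet_training):
        X, labels = diet_training
        a = em.cross_validate(X, labels, n_partitions=5, seed=9)
        b = em.cross_validate(X, labels, n_partitions=5, seed=9)
        pd.testing.assert_frame_equal(a.confusion, b.confusion)


class TestOptimalLambda:
    def test_star_tree_flat_profile_returns_zero(self):
        tree = em.read_trees(star_newick(30))[0]
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 3)), index=tree.tips)
        labels = pd.Series(rng.permutation(np.repeat(["a", "b"], 15)),
                           index=tree.tips)
        assert em.optimal_lambda(X, labels, tree.covariance()) == 0.0

    def test_clade_labels_recover_high_lambda(self):
        """A perfect root-split labelling is maximally phylogenetic."""
        tree = em.simulate_tree(150, seed=12)
        cov = tree.covariance()
        in_clade = cov.C[0] > 1e-9
        labels = pd.Series(np.where(in_clade, "x", "y"), index=cov.species)
        if labels.value_counts().min() < 2:
            pytest.skip("degenerate root split for this seed")
        X = em.simulate_bm_traits(tree, 1.0, 0.2, seed=13, n_traits=4)
        assert em.optimal_lambda(X, labels, cov) >= 0.5


class TestPFDA:
    def test_lambda_zero_equals_fda_on_ultrametric_tree(self, small_dataset,
                                                        diet_training):
        ensemble, _, _ = small_dataset
        X, labels = diet_training
        cov = ensemble[0].covariance().subset(list(X.index))
        fda = em.fda_fit(X, labels)
        pfda = em.pfda_fit(X.reindex(cov.species), labels.reindex(cov.species),
                           cov, 0.0)
        for k in range(fda.n_functions):
            r = abs(np.corrcoef(
                fda.scores.iloc[:, k].reindex(pfda.scores.index),
                pfda.scores.iloc[:, k])[0, 1])
            assert r > 1 - 1e-8

    def test_lambda_out_of_range(self, small_dataset, diet_training):
        ensemble, _, _ = small_dataset
        X, labels = diet_training
        cov = ensemble[0].covariance().subset(list(X.index))
        with pytest.raises(ValueError, match="lambda"):
            em.pfda_fit(X.reindex(cov.species),
                        labels.reindex(cov.species), cov, 1.2)

    def test_lambda_used_recorded(self, small_dataset, diet_training):
        ensemble, _, _ = small_dataset
        X, labels = diet_training
        cov = ensemble[0].covariance().subset(list(X.index))
        model = em.pfda_fit(X.reindex(cov.species),
                            labels.reindex(cov.species), cov, 0.3)
        assert model.lambda_used == 0.3


class TestWilksPower:
    def test_hand_oracle_two_groups(self):
        """Groups {1,2,3} vs {7,8,9}: Lambda = 4/58, F = 54 exactly."""
        X = pd.DataFrame({"v": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]})
        labels = ["a", "a", "a", "b", "b", "b"]
        row = em.wilks_power(X, labels).loc["v"]
        assert row["wilks_lambda"] == pytest.approx(4 / 58, abs=1e-12)
        assert row["F"] == pytest.approx(54.0, abs=1e-9)

    def test_identical_group_means(self):
        X = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        labels = ["a", "a", "a", "b", "b", "b"]
        row = em.wilks_power(X, labels).loc["v"]
        assert row["wilks_lambda"] == pytest.approx(1.0)
        assert row["F"] == pytest.approx(0.0)

    def test_f_lambda_identity_on_every_row(self, diet_training):
        X, labels = diet_training
        table = em.wilks_power(X, labels)
        n, g = len(X), labels.nunique()
        for _, row in table.iterrows():
            lhs = row["F"]
            rhs = ((1 - row["wilks_lambda"]) / row["wilks_lambda"]
                   * (n - g) / (g - 1))
            assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_constant_variable_warns(self):
        X = pd.DataFrame({"v": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0],
                          "flat": [2.0] * 6})
        labels = ["a", "a", "a", "b", "b", "b"]
        with pytest.warns(RuntimeWarning, match="constant"):
            table = em.wilks_power(X, labels)
        assert table.loc["flat", "wilks_lambda"] == 1.0
        assert table.loc["flat", "p"] == 1.0


class TestStructureCorrelations:
    def test_variable_equal_to_df1_flagged(self, diet_training):
        X, labels = diet_training
        model = em.fda_fit(X, labels)
        X2 = X.copy()
        X2["LR"] = model.scores["DF1"].reindex(X.index)
        res = em.structure_correlations(model, X2)
        assert res.r.loc["LR", "DF1"] == pytest.approx(1.0)
        assert bool(res.significant.loc["LR", "DF1"])

    def test_pure_noise_variable_unflagged(self):
        rng = np.random.default_rng(0)
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 3)),
                         columns=["a", "b", "noise"],
                         index=[f"s{i}" for i in range(n)])
        labels = pd.Series(np.repeat(["p", "q"], n // 2), index=X.index)
        X.loc[labels == "q", "a"] += 3.0
        model = em.fda_fit(X, labels)
        res = em.structure_correlations(model, X)
        assert abs(res.r.loc["noise", "DF1"]) < 0.15
        assert not bool(res.significant.loc["noise", "DF1"])

    def test_holm_adjusted_no_smaller_than_raw(self, diet_training):
        X, labels = diet_training
        model = em.fda_fit(X, labels)
        res = em.structure_correlations(model, X)
        assert (res.p_holm.to_numpy() >= res.p.to_numpy() - 1e-15).all()
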