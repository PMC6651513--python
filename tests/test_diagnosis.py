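"""ANN/SVM/NB classifiers, majority voting, metrics, dice, k-fold CV."""

import itertools

import numpy as np
import pytest

from retfuse.diagnosis import (
    ConfusionCounts,
    FeatureScaler,
    classification_metrics,
    dice,
    kfold_cv,
    majority_label,
    predict_ensemble,
    train_ann,
    train_nb,
    train_svm,
)


def _separable_features(n=40, dim=16, gap=4.0, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (n, dim))
    y = (np.arange(n) % 2).astype(int)
    x[y == 1, 0] += gap
    return x, y


class TestANN:
    def test_architecture_hidden_widths(self):
        x, y = _separable_features()
        model = train_ann(x, y, seed=1, epochs=50)
        widths = [l.params["W"].shape[1] for l in model.net.layers if hasattr(l, "of")]
        assert widths == [12, 9, 2]

    def test_separable_data_fit_perfectly(self):
        x, y = _separable_features(seed=1)
        scaler = FeatureScaler.fit(x)
        model = train_ann(scaler.transform(x), y, seed=1)
        assert (model.predict(scaler.transform(x)) == y).mean() == 1.0

    def test_same_seed_identical_weights(self):
        x, y = _separable_features(seed=2)
        m1 = train_ann(x, y, seed=7, epochs=100)
        m2 = train_ann(x, y, seed=7, epochs=100)
        for l1, l2 in zip(m1.net.layers, m2.net.layers):
            for k in l1.params:
                assert np.array_equal(l1.params[k], l2.params[k])

    def test_single_class_rejected(self):
        x = np.zeros((10, 16))
        with pytest.raises(ValueError):
            train_ann(x, np.zeros(10, int))


class TestSVM:
    def test_xor_pattern_solved_by_rbf(self):
        x = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 10, float)
        x += np.random.default_rng(0).normal(0, 0.05, x.shape)
        y = (x.round()[:, 0].astype(int) ^ x.round()[:, 1].astype(int))
        model = train_svm(x, y, kernel="rbf", gamma=2.0)
        assert (model.predict(x) == y).mean() == 1.0

    def test_rbf_beats_linear_on_circular_data(self):
        rng = np.random.default_rng(5)
        n = 200
        r = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(2, 3, n // 2)])
        theta = rng.uniform(0, 2 * np.pi, n)
        x = np.c_[r * np.cos(theta), r * np.sin(theta)]
        y = (r > 1.5).astype(int)
        from sklearn.svm import SVC

        rbf_acc = (train_svm(x, y, kernel="rbf", gamma=1.0).predict(x) == y).mean()
        lin = SVC(kernel="linear").fit(x, y)
        assert rbf_acc >= (lin.predict(x) == y).mean()

    def test_mlp_kernel_accepted_and_trains(self):
        x, y = _separable_features(dim=4, seed=3)
        model = train_svm(x, y, kernel="mlp", mlp_scale=0.25, mlp_offset=-1.0)
        assert set(np.unique(model.predict(x))) <= {0, 1}

    def test_unknown_kernel_rejected(self):
        x, y = _separable_features(dim=4)
        with pytest.raises(ValueError):
            train_svm(x, y, kernel="poly")

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            train_svm([], None)


class TestNaiveBayes:
    def test_symmetric_midpoint_decision_boundary(self):
        # two 1-D classes N(0,1) and N(4,1) with equal priors: boundary at 2
        x = np.concatenate([np.zeros(500), np.full(500, 4.0)])[:, None]
        y = np.concatenate([np.zeros(500, int), np.ones(500, int)])
        rng = np.random.default_rng(0)
        x = x + rng.normal(0, 1, x.shape)
        model = train_nb(x, y)
        # force exact symmetric parameters to test the decision rule itself
        model.priors = np.array([0.5, 0.5])
        model.means = np.array([[0.0], [4.0]])
        model.variances = np.array([[1.0], [1.0]])
        assert model.predict(np.array([[1.9]]))[0] == 0
        assert model.predict(np.array([[2.1]]))[0] == 1

    def test_posterior_matches_direct_bayes_oracle(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(2, 1.5, (30, 2))])
        y = np.repeat([0, 1], 30)
        model = train_nb(x, y)
        query = rng.normal(1, 1, (20, 2))
        got = model.predict_proba(query)
        # direct Bayes rule with Gaussian likelihoods, per feature
        def gauss(v, mu, var):
            return np.exp(-((v - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)

        for i, q in enumerate(query):
            joint = []
            for k in (0, 1):
                lik = np.prod([gauss(q[j], model.means[k, j], model.variances[k, j])
                               for j in range(2)])
                joint.append(model.priors[k] * lik)
            posterior = joint[1] / (joint[0] + joint[1])
            assert abs(got[i, 1] - posterior) < 1e-12

    def test_unequal_priors_shift_boundary_by_closed_form(self):
        model = train_nb(np.array([[0.0], [4.0], [0.1], [3.9]]), np.array([0, 1, 0, 1]))
        model.priors = np.array([0.9, 0.1])
        model.means = np.array([[0.0], [4.0]])
        sigma2 = 1.0
        model.variances = np.array([[sigma2], [sigma2]])
        # boundary: x* = 2 + ln(0.9/0.1) * sigma2 / 4
        x_star = 2 + np.log(9) * sigma2 / 4
        eps = 1e-6
        assert model.predict(np.array([[x_star - eps]]))[0] == 0
        assert model.predict(np.array([[x_star + eps]]))[0] == 1

    def test_agrees_with_sklearn_gaussian_nb(self):
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(13)
        x = np.vstack([rng.normal(0, 1, (50, 16)), rng.normal(1, 2, (50, 16))])
        y = np.repeat([0, 1], 50)
        ours = train_nb(x, y)
        theirs = GaussianNB(var_smoothing=0).fit(x, y)
        q = rng.normal(0.5, 1, (30, 16))
        assert np.array_equal(ours.predict(q), theirs.predict(q))


class TestEnsemble:
    class _Fixed:
        def __init__(self, label):
            self.label = label

        def predict(self, x):
            return np.array([self.label])

        def predict_proba(self, x):
            p = np.zeros((1, 2))
            p[0, self.label] = 1.0
            return p

    @pytest.mark.parametrize("votes", list(itertools.product([0, 1], repeat=3)))
    def test_final_label_is_mode_for_all_vote_patterns(self, votes):
        a, s, n = (self._Fixed(v) for v in votes)
        diag = predict_ensemble(a, s, n, np.zeros(16))
        expect = "me" if sum(votes) >= 2 else "healthy"
        assert diag.final == expect
        assert diag.final == majority_label(diag.votes)

    def test_votes_recorded_per_classifier(self):
        diag = predict_ensemble(self._Fixed(1), self._Fixed(1), self._Fixed(0), np.zeros(16))
        assert diag.votes == {"ann": "me", "svm": "me", "nb": "healthy"}
        assert diag.final == "me"


class TestClassificationMetrics:
    def test_printed_confusion_counts_reproduce_reported_metrics(self):
        """The hybrid classifier's published confusion counts on 5100
        validation scans: TP=2473, TN=2338, FP=212, FN=77."""
        counts = ConfusionCounts(tp=2473, tn=2338, fp=212, fn=77)
        m = classification_metrics(counts)
        assert counts.tp + counts.tn == 4811
        assert m.accuracy * 100 == pytest.approx(94.33, abs=0.005)
        assert m.sensitivity == pytest.approx(2473 / 2550)
        assert round(m.sensitivity, 2) == 0.97
        assert round(m.specificity, 2) == 0.92
        assert round(m.ppv, 2) == 0.92
        assert round(m.npv, 2) == 0.97

    @pytest.mark.parametrize(
        "tp,tn,fp,fn,se,sp",
        [
            (2457, 2291, 259, 93, 0.96, 0.90),   # ANN row
            (2407, 2322, 228, 143, 0.94, 0.91),  # SVM row
            (2374, 2289, 261, 176, 0.93, 0.90),  # NB row
        ],
    )
    def test_individual_classifier_rows(self, tp, tn, fp, fn, se, sp):
        m = classification_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert round(m.sensitivity, 2) == se
        assert round(m.specificity, 2) == sp

    def test_symmetric_counts_give_half(self):
        m = classification_metrics(ConfusionCounts(1, 1, 1, 1))
        assert m.sensitivity == m.specificity == m.ppv == m.npv == m.accuracy == 0.5

    def test_metric_identities(self):
        c = ConfusionCounts(37, 22, 5, 11)
        m = classification_metrics(c)
        assert m.sensitivity * (c.tp + c.fn) == pytest.approx(c.tp)
        w_pos = (c.tp + c.fn) / c.total
        w_neg = (c.tn + c.fp) / c.total
        assert m.accuracy == pytest.approx(w_pos * m.sensitivity + w_neg * m.specificity)

    def test_undefined_metric_reported_as_none(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.sensitivity is None and m.ppv is None
        assert m.accuracy == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts())


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.random.default_rng(1).random((10, 10)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :2] = True
        b[0, 1:3] = True
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros((5, 5), bool), np.zeros((5, 5), bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestKFoldCV:
    @staticmethod
    def _nb_trainer(x, y):
        return train_nb(x, y)

    def test_stratified_fold_sizes(self):
        x, y = _separable_features(n=10, dim=4)
        res = kfold_cv(self._nb_trainer, x, y, k=2, seed=0)
        assert len(res["fold_accuracies"]) == 2

    def test_separable_features_reach_max_accuracy_one(self):
        x, y = _separable_features(n=60, gap=8.0)
        for k in (2, 5):
            res = kfold_cv(self._nb_trainer, x, y, k=k, seed=1)
            assert res["max_accuracy"] == 1.0

    def test_same_seed_same_folds(self):
        x, y = _separable_features(n=30)
        r1 = kfold_cv(self._nb_trainer, x, y, k=3, seed=5)
        r2 = kfold_cv(self._nb_trainer, x, y, k=3, seed=5)
        assert r1["fold_accuracies"] == r2["fold_accuracies"]

    def test_k_larger_than_n_rejected(self):
        x, y = _separable_features(n=6, dim=4)
        with pytest.raises(ValueError):
            kfold_cv(self._nb_trainer, x, y, k=10)
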