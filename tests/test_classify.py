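"""AUC, lasso-path classification, and pluggable signature backends."""

import numpy as np
import pandas as pd
import pytest

from deepradiomics.classify import (BACKENDS, LassoPathClassifier, auc,
                                    classify_clinical, classify_signatures,
                                    lasso_path_fit)


def _brute_force_auc(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_hand_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    def test_exactly_matches_pair_counting(self):
        """Rank-based AUC equals all-pairs counting on 100 random instances."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 50))
            scores = rng.integers(0, 10, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(
                _brute_force_auc(scores, labels), abs=1e-12)


@pytest.fixture(scope="module")
def labelled_data():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 25))
    z = X[:, 0]
    y = (rng.random(200) < 1 / (1 + np.exp(-2.5 * z))).astype(float)
    return X, y


class TestLassoPath:
    def test_all_slopes_zero_at_lambda_max(self, labelled_data):
        X, y = labelled_data
        path = LassoPathClassifier(n_lambda=25, seed=0).fit(X, y)
        assert path.n_nonzero_[0] == 0
        np.testing.assert_array_equal(path.path_coefs_[0], 0.0)
        # the empty model scores every sample identically -> chance AUC
        assert auc(X @ path.path_coefs_[0], y) == 0.5
        assert path.n_nonzero_[-1] >= path.n_nonzero_[0]
        assert len(path.lambda_grid_) == 25
        assert (np.diff(path.lambda_grid_) < 0).all()

    def test_informative_feature_enters_path_first(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=200)
        y = (z + 0.3 * rng.normal(size=200) > 0).astype(float)
        X = rng.normal(size=(200, 15))
        X[:, 4] = z + 0.1 * rng.normal(size=200)
        path = LassoPathClassifier(n_lambda=40, seed=0).fit(X, y)
        first = next(i for i in range(40) if path.n_nonzero_[i] > 0)
        active = np.flatnonzero(np.abs(path.path_coefs_[first]) > 1e-10)
        assert active.tolist() == [4]

    def test_split_fit_is_deterministic(self, labelled_data):
        X, y = labelled_data
        a = lasso_path_fit(X, y, n_lambda=10, seed=3)
        b = lasso_path_fit(X, y, n_lambda=10, seed=3)
        np.testing.assert_array_equal(a.cv_auc, b.cv_auc)
        assert a.best_lambda == b.best_lambda and a.test_auc == b.test_auc

    def test_strong_signal_gives_high_test_auc(self, labelled_data):
        X, y = labelled_data
        res = lasso_path_fit(X, y, n_lambda=30, seed=0)
        assert res.test_auc > 0.8

    def test_missing_labels_are_excluded(self, labelled_data):
        X, y = labelled_data
        y2 = y.copy()
        y2[:10] = np.nan
        res = lasso_path_fit(X, y2, n_lambda=10, seed=0)
        assert res.test_auc > 0.5

    def test_degenerate_labels_rejected(self, labelled_data):
        X, _ = labelled_data
        with pytest.raises(ValueError, match="degenerate"):
            lasso_path_fit(X, np.ones(200), n_lambda=5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="20 samples"):
            lasso_path_fit(np.zeros((10, 3)), np.tile([0.0, 1.0], 5))

    def test_label_permutation_control(self, labelled_data):
        """Mean held-out AUC over label permutations stays near chance."""
        X, y = labelled_data
        rng = np.random.default_rng(4)
        aucs = []
        for _ in range(20):
            res = lasso_path_fit(X[:, :10], rng.permutation(y), n_lambda=8,
                                 cv_folds=3, seed=5)
            aucs.append(res.test_auc)
        assert 0.4 <= np.mean(aucs) <= 0.6


class TestClassifyClinical:
    def test_image_level_labels_propagate_from_patients(self):
        rng = np.random.default_rng(5)
        pids = np.repeat([f"p{i:02d}" for i in range(40)], 3)
        z = np.repeat(rng.normal(size=40), 3)
        feats = pd.DataFrame({
            "image_id": [f"i{k}" for k in range(120)],
            "patient_id": pids,
            "f1": z + 0.2 * rng.normal(size=120),
            "f2": rng.normal(size=120),
        })
        clinical = pd.DataFrame(
            {"L": (rng.normal(size=40) * 0.3 + rng.normal(size=40) * 0
                   + z[::3] > 0).astype(float),
             "EMPTY": np.nan},
            index=[f"p{i:02d}" for i in range(40)])
        with pytest.warns(UserWarning, match="EMPTY"):
            results = classify_clinical(feats, clinical, n_lambda=10,
                                        cv_folds=3, seed=0)
        assert set(results) == {"L"}
        assert results["L"].test_auc > 0.8

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            classify_clinical(pd.DataFrame(), pd.DataFrame(), level="slice")


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(200, 8))
    targets = pd.DataFrame({"sig": (X[:, 2] > 0.6).astype(float)})
    return X, targets


class TestClassifySignatures:
    @pytest.mark.parametrize("backend", BACKENDS)
    def test_separable_target_scores_high(self, separable, backend):
        X, targets = separable
        out = classify_signatures(X, targets, backend=backend, seed=0)
        assert out.loc[0, "auc"] >= 0.95

    @pytest.mark.parametrize("backend", BACKENDS)
    def test_shuffled_target_scores_near_chance(self, separable, backend):
        """Mean held-out AUC over shuffles sits in the chance band 0.5 +/- 0.1."""
        X, targets = separable
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(5):
            shuffled = pd.DataFrame(
                {"sig": rng.permutation(targets["sig"].to_numpy())})
            out = classify_signatures(X, shuffled, backend=backend, seed=0)
            aucs.append(out.loc[0, "auc"])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_length_mismatch_rejected(self, separable):
        X, targets = separable
        with pytest.raises(ValueError, match="misaligned"):
            classify_signatures(X[:50], targets)

    def test_unknown_backend_names_available(self, separable):
        X, targets = separable
        with pytest.raises(ValueError, match="neural-net"):
            classify_signatures(X, targets, backend="svm")
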