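import numpy as np
import pytest

import vibrafall as vf
from vibrafall.mfss_svm import (
    MFSSSVMClassifier,
    fit_base,
    infer_n_sensors,
    select_semi_labels,
)

from conftest import make_two_cluster_views


def semi_mask_labels(y, rate, seed):
    rng = np.random.default_rng(seed)
    out = np.zeros_like(y)
    for c in (-1, 1):
        idx = np.flatnonzero(y == c)
        keep = rng.choice(idx, size=max(1, int(rate * idx.size)), replace=False)
        out[keep] = c
    return out


class TestInferNSensors:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_round_trip(self, n):
        d = 2 * n + n * (n - 1) // 2
        assert infer_n_sensors(d) == n

    @pytest.mark.parametrize("d", [3, 6, 8, 100])
    def test_invalid_width_rejected(self, d):
        with pytest.raises(ValueError, match="feature width"):
            infer_n_sensors(d)


class TestFitBase:
    def test_separable_clusters_fit_perfectly(self):
        X = np.array([[-10.0], [-11.0], [-9.5], [10.0], [11.0], [9.5]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        clf = fit_base(X, y, C=1.0)
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_single_class_error_names_counts(self):
        with pytest.raises(ValueError, match="0 fall"):
            fit_base(np.zeros((4, 2)), [-1, -1, -1, -1])

    def test_refit_is_deterministic(self):
        X, y = make_two_cluster_views(seed=1)
        d1 = fit_base(X, y).decision_function(X)
        d2 = fit_base(X, y).decision_function(X)
        np.testing.assert_array_equal(d1, d2)

    def test_xor_geometry_learned_by_rbf(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.08, size=(25, 2)) for c in centers])
        y = np.repeat([1, 1, -1, -1], 25)
        clf = fit_base(X, y, C=10.0)
        assert np.mean(clf.predict(X) == y) > 0.9


class TestSelectSemiLabels:
    def test_empty_when_all_outside_band(self):
        dec = np.array([1.5, -2.0, 3.1])
        sel, lab = select_semi_labels(dec, np.ones(3, int), np.ones(3, int), cap=0.5)
        assert sel.size == 0 and lab.size == 0

    def test_near_margin_point_with_agreeing_peers_selected(self):
        dec = np.array([0.99, 5.0])
        sel, lab = select_semi_labels(
            dec, np.array([1, 1]), np.array([1, -1]), cap_count=5
        )
        assert sel.tolist() == [0]
        assert lab.tolist() == [1]

    def test_matches_brute_force_reranking(self):
        rng = np.random.default_rng(4)
        dec = rng.normal(0, 1.2, size=200)
        p1 = rng.choice([-1, 1], size=200)
        p2 = rng.choice([-1, 1], size=200)
        cap_count = 13
        sel, lab = select_semi_labels(dec, p1, p2, cap_count=cap_count)
        # oracle: filter then sort the full candidate list explicitly
        cands = [
            (abs(abs(dec[i]) - 1.0), i)
            for i in range(200)
            if 0 < abs(dec[i]) <= 1.0 and p1[i] == p2[i] and p1[i] != 0
        ]
        cands.sort()
        expected = [i for _, i in cands[:cap_count]]
        assert sorted(sel.tolist()) == sorted(expected)
        np.testing.assert_array_equal(lab, p1[sel])

    def test_requires_some_cap(self):
        with pytest.raises(ValueError, match="cap"):
            select_semi_labels(np.zeros(3), np.ones(3, int), np.ones(3, int))


class TestMFSSSVMClassifier:
    def test_full_labeling_equals_supervised(self):
        X, y = make_two_cluster_views(seed=2)
        semi = MFSSSVMClassifier().fit(X, y)
        sup = MFSSSVMClassifier(max_iter=0).fit(X, y)
        np.testing.assert_array_equal(semi.predict(X), sup.predict(X))
        assert semi.n_iter_ == 1
        assert semi.history_[0]["added_total"] == 0
        assert semi.stop_reason_ == "converged"

    def test_max_iter_zero_is_supervised_path(self):
        X, y = make_two_cluster_views(seed=3)
        y_semi = semi_mask_labels(y, 0.3, seed=3)
        clf = MFSSSVMClassifier(max_iter=0).fit(X, y_semi)
        assert clf.stop_reason_ == "supervised"
        assert clf.history_ == []
        assert clf.semi_indices_.size == 0

    def test_semi_rows_subset_of_unlabeled(self):
        X, y = make_two_cluster_views(n_per_class=100, sep=2.0, seed=4)
        y_semi = semi_mask_labels(y, 0.2, seed=4)
        clf = MFSSSVMClassifier(
            error_gate=False, strict_peer_check=False, validate=False
        ).fit(X, y_semi)
        unlabeled = set(np.flatnonzero(y_semi == 0))
        assert set(clf.semi_indices_).issubset(unlabeled)

    def test_history_conservation(self):
        """Total additions minus removals equals the final pseudo-label count
        (summed over the three per-view sets)."""
        X, y = make_two_cluster_views(n_per_class=100, sep=2.0, seed=5)
        y_semi = semi_mask_labels(y, 0.2, seed=5)
        clf = MFSSSVMClassifier(
            error_gate=False, strict_peer_check=False, validate=False
        ).fit(X, y_semi)
        added = sum(h["added_total"] for h in clf.history_)
        removed = sum(h["removed"] for h in clf.history_)
        assert added - removed == sum(len(s) for s in clf.semi_per_view_)
        assert added > 0  # the scheme actually engaged on this data

    def test_vote_equals_mode_of_view_votes(self):
        X, y = make_two_cluster_views(n_per_class=80, sep=1.5, seed=6)
        clf = MFSSSVMClassifier(max_iter=0).fit(X, y)
        rng = np.random.default_rng(0)
        Xnew = rng.normal(1.0, 2.0, size=(50, 5))
        votes = clf.predict_views(Xnew)
        pred = clf.predict(Xnew)
        for v, p in zip(votes, pred):
            vals, counts = np.unique(v, return_counts=True)
            assert p == vals[np.argmax(counts)]

    def test_three_voters_never_tie(self):
        X, y = make_two_cluster_views(seed=7)
        clf = MFSSSVMClassifier(max_iter=0).fit(X, y)
        votes = clf.predict_views(X)
        assert np.all(votes.sum(axis=1) != 0)

    def test_single_class_labels_rejected(self):
        X, _ = make_two_cluster_views(seed=8)
        with pytest.raises(ValueError, match="both classes"):
            MFSSSVMClassifier().fit(X, np.ones(X.shape[0], dtype=int))

    def test_width_mismatch_at_predict_rejected(self):
        X, y = make_two_cluster_views(seed=9)
        clf = MFSSSVMClassifier(max_iter=0).fit(X, y)
        with pytest.raises(ValueError, match="width"):
            clf.predict(X[:, :4])

    def test_invalid_label_values_rejected(self):
        X, _ = make_two_cluster_views(seed=10)
        with pytest.raises(ValueError, match="labels"):
            MFSSSVMClassifier().fit(X, np.full(X.shape[0], 2))

    def test_semi_supervision_does_not_hurt_two_cluster_data(self):
        """Paired comparison over 10 seeds: the co-trained ensemble must be
        at least as accurate on held-out data as its supervised start."""
        gains = []
        for seed in range(10):
            X, y = make_two_cluster_views(n_per_class=120, sep=2.0, seed=seed)
            X_train, y_train = X[:160], y[:160]
            X_test, y_test = X[160:], y[160:]
            y_semi = semi_mask_labels(y_train, 0.2, seed=seed)
            sup = MFSSSVMClassifier(max_iter=0).fit(X_train, y_semi)
            semi = MFSSSVMClassifier().fit(X_train, y_semi)
            gains.append(
                np.mean(semi.predict(X_test) == y_test)
                - np.mean(sup.predict(X_test) == y_test)
            )
        assert np.mean(gains) >= 0.0

    def test_sklearn_clone_and_get_params(self):
        from sklearn.base import clone

        clf = MFSSSVMClassifier(C=2.0, max_iter=5)
        clone_ = clone(clf)
        assert clone_.get_params()["C"] == 2.0
        assert clone_.get_params()["max_iter"] == 5


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = make_two_cluster_views(seed=12)
        clf = MFSSSVMClassifier().fit(X, y)
        vf.save_model(clf, tmp_path / "model.joblib")
        back = vf.load_model(tmp_path / "model.joblib")
        np.testing.assert_array_equal(back.predict(X), clf.predict(X))
        assert back.history_ == clf.history_

    def test_unfitted_model_rejected(self, tmp_path):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            vf.save_model(MFSSSVMClassifier(), tmp_path / "m.joblib")


class TestLabelingRateExperiment:
    def test_full_rate_initial_equals_final(self, tiny_dataset):
        tab = vf.labeling_rate_experiment(
            tiny_dataset, rates=[1.0], split=0.6, n_repeats=2, seed=0
        )
        assert tab.loc[0, "initial_accuracy"] == tab.loc[0, "final_accuracy"]
        assert tab.loc[0, "relative_gain"] == 0.0

    def test_output_schema(self, tiny_dataset):
        tab = vf.labeling_rate_experiment(
            tiny_dataset, rates=[0.5], split=0.6, n_repeats=1, seed=0
        )
        assert list(tab.columns) == [
            "rate", "initial_accuracy", "final_accuracy", "relative_gain",
            "sensitivity", "specificity",
        ]

    def test_gain_column_uses_relative_change_formula(self, tiny_dataset):
        tab = vf.labeling_rate_experiment(
            tiny_dataset, rates=[0.5, 1.0], split=0.6, n_repeats=2, seed=1
        )
        for _, row in tab.iterrows():
            expected = round(
                100 * (row.final_accuracy - row.initial_accuracy) / row.initial_accuracy,
                2,
            )
            assert row.relative_gain == expected

    @pytest.mark.parametrize("rates", [[0.0], [1.5]])
    def test_invalid_rates_rejected(self, tiny_dataset, rates):
        with pytest.raises(ValueError, match="rates"):
            vf.labeling_rate_experiment(tiny_dataset, rates=rates)

    def test_invalid_split_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="split"):
            vf.labeling_rate_experiment(tiny_dataset, rates=[0.5], split=1.2)
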