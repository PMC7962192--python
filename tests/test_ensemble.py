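import numpy as np
import pandas as pd
import pytest

from prednts.ensemble import (
    PAPER_WEIGHTS,
    EnsembleError,
    EnsembleLoadError,
    FusionWeights,
    PredNTS,
    fuse_scores,
    load_ensemble,
    optimize_weights,
    predict_single,
    save_ensemble,
    stage_seed,
    train_single,
)
from prednts.evaluation import pairwise_auc, stratified_folds
from prednts.feature_selection import SelectedSubset
from prednts.sequence_io import labels_array

SCHEMES = ("binary", "aaindex", "cksaap", "kmer")


def toy_matrix(n=80, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    shift = 3.0 if separable else 0.0
    X = pd.DataFrame(
        y[:, None] * shift + rng.normal(0, 1, (n, 6)),
        columns=[f"f{i}" for i in range(6)],
    )
    subset = SelectedSubset("kmer", tuple(X.columns), {6: 1.0}, 6)
    return X, y, subset


class TestFusionWeights:
    def test_paper_weights_are_valid_and_sum_to_one(self):
        fw = FusionWeights(PAPER_WEIGHTS)
        assert fw.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_or_unnormalized_rejected(self):
        with pytest.raises(EnsembleError):
            FusionWeights({"binary": -0.1, "aaindex": 0.4, "cksaap": 0.4, "kmer": 0.3})
        with pytest.raises(EnsembleError):
            FusionWeights({"binary": 0.5, "aaindex": 0.5, "cksaap": 0.5, "kmer": 0.5})
        with pytest.raises(EnsembleError, match="missing"):
            FusionWeights({"binary": 1.0})


class TestFuseScores:
    def test_unit_probabilities_fuse_to_one(self):
        probs = {s: np.ones(3) for s in SCHEMES}
        fused = fuse_scores(probs, FusionWeights(PAPER_WEIGHTS))
        assert np.allclose(fused, 1.0)

    def test_vertex_weight_is_identity(self):
        rng = np.random.default_rng(0)
        probs = {s: rng.random(10) for s in SCHEMES}
        fw = FusionWeights({"binary": 0, "aaindex": 0, "cksaap": 0, "kmer": 1.0})
        assert np.array_equal(fuse_scores(probs, fw), probs["kmer"])

    def test_hand_arithmetic(self):
        probs = {
            "binary": [0.0], "aaindex": [1.0], "cksaap": [0.5], "kmer": [0.5],
        }
        fw = FusionWeights({s: 0.25 for s in SCHEMES})
        assert fuse_scores(probs, fw)[0] == pytest.approx(0.5)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(1)
        probs = {s: rng.random(50) for s in SCHEMES}
        fused = fuse_scores(probs, FusionWeights(PAPER_WEIGHTS))
        stacked = np.stack([probs[s] for s in SCHEMES])
        assert (fused >= stacked.min(axis=0) - 1e-12).all()
        assert (fused <= stacked.max(axis=0) + 1e-12).all()

    def test_length_mismatch_is_error(self):
        probs = {s: np.ones(3) for s in SCHEMES}
        probs["kmer"] = np.ones(4)
        with pytest.raises(EnsembleError, match="length"):
            fuse_scores(probs, FusionWeights(PAPER_WEIGHTS))


class TestTrainPredictSingle:
    def test_overfit_sanity_on_separable_data(self):
        X, y, subset = toy_matrix(separable=True)
        model = train_single(X, y, subset, n_trees=100, seed=0)
        probs = predict_single(model, X)
        assert pairwise_auc(probs, y) == 1.0
        assert probs[y == 1].min() > 0.5

    def test_deterministic_given_seed(self):
        X, y, subset = toy_matrix()
        p1 = predict_single(train_single(X, y, subset, seed=5, n_trees=50), X)
        p2 = predict_single(train_single(X, y, subset, seed=5, n_trees=50), X)
        assert np.array_equal(p1, p2)

    def test_probabilities_in_unit_interval_and_duplicates_agree(self):
        X, y, subset = toy_matrix(separable=False)
        model = train_single(X, y, subset, n_trees=50, seed=1)
        X2 = pd.concat([X.iloc[[0]], X.iloc[[0]]])
        p = predict_single(model, X2)
        assert p[0] == p[1]
        assert ((p >= 0) & (p <= 1)).all()

    def test_missing_subset_feature_is_schema_error(self):
        X, y, subset = toy_matrix()
        bad = SelectedSubset("kmer", ("f0", "ghost"), {2: 1.0}, 2)
        with pytest.raises(EnsembleError, match="ghost"):
            train_single(X, y, bad, n_trees=10, seed=0)
        model = train_single(X, y, subset, n_trees=10, seed=0)
        with pytest.raises(EnsembleError, match="missing"):
            predict_single(model, X[["f0", "f1"]])

    def test_label_permutation_yields_chance_level_cv(self):
        X, y, subset = toy_matrix(n=100, separable=True)
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(y)
            fold_aucs = []
            for tr, te in stratified_folds(y_perm, 5, seed):
                m = train_single(X.iloc[tr], y_perm[tr], subset, n_trees=30,
                                 seed=seed)
                fold_aucs.append(pairwise_auc(predict_single(m, X.iloc[te]),
                                              y_perm[te]))
            aucs.append(np.mean(fold_aucs))
        assert 0.4 <= np.mean(aucs) <= 0.6

    @pytest.mark.parametrize("algorithm", ["nb", "knn"])
    def test_comparators_share_contracts(self, algorithm):
        X, y, subset = toy_matrix(separable=True)
        model = train_single(X, y, subset, n_trees=10, seed=0, algorithm=algorithm)
        p1 = predict_single(model, X)
        p2 = predict_single(model, X)
        assert ((p1 >= 0) & (p1 <= 1)).all()
        assert np.array_equal(p1, p2)
        assert pairwise_auc(p1, y) > 0.9  # separable data


class TestOptimizeWeights:
    def test_planted_optimum_recovered(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 100)
        probs = {s: rng.random(200) for s in SCHEMES}
        probs["cksaap"] = y.astype(float)
        fw = optimize_weights(probs, y)
        assert fw.weights["cksaap"] >= 0.9

    def test_identical_schemes_tie_break_to_vertex(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 50)
        shared = rng.random(100)
        probs = {s: shared for s in SCHEMES}
        fw = optimize_weights(probs, y)
        assert max(fw.weights.values()) == pytest.approx(1.0)

    def test_contract_simplex(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 30)
        probs = {s: rng.random(60) for s in SCHEMES}
        fw = optimize_weights(probs, y)
        vals = fw.as_array()
        assert (vals >= 0).all()
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_labels_rejected(self):
        probs = {s: np.ones(4) for s in SCHEMES}
        with pytest.raises(EnsembleError):
            optimize_weights(probs, np.ones(4, dtype=int))


class TestEnsembleRoundTrip:
    def test_save_load_predicts_identically(self, tiny_model, fixture_windows,
                                            tmp_path):
        path = tmp_path / "model.joblib"
        before = tiny_model.decision_scores(fixture_windows[:12])
        save_ensemble(tiny_model.ensemble_, path)
        loaded = load_ensemble(path)
        after_scores = tiny_model.decision_scores(fixture_windows[:12])
        from prednts.ensemble import ensemble_predict

        loaded_scores = ensemble_predict(loaded, fixture_windows[:12])
        assert np.array_equal(before["score"], loaded_scores["score"])
        assert np.array_equal(before["score"], after_scores["score"])

    def test_corrupted_file_is_load_error(self, tmp_path):
        path = tmp_path / "junk.joblib"
        path.write_bytes(b"not a model at all")
        with pytest.raises(EnsembleLoadError):
            load_ensemble(path)

    def test_foreign_payload_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "other.joblib"
        joblib.dump({"something": 1}, path)
        with pytest.raises(EnsembleLoadError, match="not a prednts"):
            load_ensemble(path)


class TestPredNTSEstimator:
    def test_fitted_attributes_and_probability_contract(self, tiny_model,
                                                        fixture_windows):
        assert set(tiny_model.subsets_) == set(SCHEMES)
        proba = tiny_model.predict_proba(fixture_windows[:8])
        assert proba.shape == (8, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        preds = tiny_model.predict(fixture_windows[:8])
        assert set(np.unique(preds)) <= {0, 1}

    def test_fused_oof_auc_not_below_best_single_when_optimized(
        self, fixture_windows
    ):
        est = PredNTS(w=5, K_values=(1,), feature_selection=False, n_trees=40,
                      cv_folds=3, weights="optimize", random_state=3)
        est.fit(fixture_windows)
        y = labels_array(fixture_windows)
        fused = pairwise_auc(est.fused_oof_, y)
        singles = [pairwise_auc(est.oof_scores_[s], y) for s in SCHEMES]
        assert fused >= max(singles) - 1e-12

    def test_refit_with_same_seed_is_identical(self, fixture_windows):
        kwargs = dict(w=5, K_values=(1,), feature_selection=False, n_trees=40,
                      cv_folds=3, weights=PAPER_WEIGHTS, random_state=9)
        a = PredNTS(**kwargs).fit(fixture_windows)
        b = PredNTS(**kwargs).fit(fixture_windows)
        probe = fixture_windows[:10]
        assert np.array_equal(
            a.decision_scores(probe)["score"], b.decision_scores(probe)["score"]
        )
        assert a.cv_summary_.equals(b.cv_summary_)

    def test_sklearn_params_clone_roundtrip(self):
        from sklearn.base import clone

        est = PredNTS(w=7, n_trees=123)
        cloned = clone(est)
        assert cloned.get_params()["w"] == 7
        assert cloned.get_params()["n_trees"] == 123

    def test_single_class_labels_rejected(self, fixture_windows):
        est = PredNTS(w=5, feature_selection=False)
        with pytest.raises(EnsembleError):
            est.fit(fixture_windows, np.zeros(len(fixture_windows), dtype=int))


def test_stage_seed_is_deterministic_and_bounded():
    assert stage_seed(1, "cv") == stage_seed(1, "cv")
    assert stage_seed(1, "cv") != stage_seed(2, "cv")
    assert stage_seed(1, "cv") != stage_seed(1, "final:kmer")
    assert 0 <= stage_seed(123456789, "x") < 2**31
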