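"""Stratified splitting, backend training, probability contracts, tuning."""

from __future__ import annotations

import numpy as np
import pytest

from lulcfuse.classify import (
    KINDS,
    default_hyperparameters,
    load_model,
    predict_proba,
    save_model,
    stratified_split,
    train_backend,
    triangular_weights,
    tune_hyperparameters,
)
from lulcfuse.types import ClassScheme, FeatureTable, SampleSet


def _blobs(rng, n_per_class=60, n_classes=3, p=5, sep=6.0):
    x = np.vstack(
        [rng.normal(i * sep, 1.0, (n_per_class, p)) for i in range(n_classes)]
    )
    y = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    return x, y


def _sample_set(codes):
    n = codes.size
    return SampleSet(rows=np.zeros(n, np.intp), cols=np.arange(n), codes=codes)


class TestStratifiedSplit:
    def test_rounding_rule_70_30(self):
        codes = np.repeat(1, 186)
        ss = stratified_split(_sample_set(codes), 0.7, seed=0)
        assert (ss.split == "train").sum() == 130
        assert (ss.split == "test").sum() == 56

    def test_seeds_change_membership_not_counts(self):
        codes = np.repeat([1, 2], 50)
        a = stratified_split(_sample_set(codes), 0.7, seed=1)
        b = stratified_split(_sample_set(codes), 0.7, seed=2)
        assert (a.split == "train").sum() == (b.split == "train").sum() == 70
        assert not np.array_equal(a.split, b.split)

    def test_deterministic_given_seed(self):
        codes = np.repeat([1, 2, 3], 30)
        a = stratified_split(_sample_set(codes), 0.7, seed=9)
        b = stratified_split(_sample_set(codes), 0.7, seed=9)
        assert np.array_equal(a.split, b.split)

    def test_tiny_class_keeps_both_splits_populated(self):
        # documented boundary: rounding is clamped so neither split empties
        codes = np.array([1, 1])
        ss = stratified_split(_sample_set(codes), 0.999, seed=0)
        assert set(ss.split) == {"train", "test"}

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            stratified_split(_sample_set(np.array([1, 2, 2])), 0.7, seed=0)


class TestBackends:
    @pytest.mark.parametrize("kind", KINDS)
    def test_separable_blobs_high_accuracy(self, kind, rng):
        x, y = _blobs(rng)
        test_x, test_y = _blobs(np.random.default_rng(99))
        model = train_backend(kind, x, codes=y, seed=0)
        probs = predict_proba(model, test_x)
        pred = np.asarray(model.classes)[probs.argmax(axis=1)]
        assert (pred == test_y).mean() > 0.95

    @pytest.mark.parametrize("kind", KINDS)
    def test_probabilities_on_simplex(self, kind, rng):
        x, y = _blobs(rng, n_per_class=30)
        model = train_backend(kind, x, codes=y, seed=0)
        probs = predict_proba(model, rng.normal(3, 4, (50, x.shape[1])))
        assert probs.min() >= 0
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("kind", ["rf", "wknn", "ann", "nb"])
    def test_argmax_matches_native_hard_prediction(self, kind, rng):
        x, y = _blobs(rng, n_per_class=40, sep=2.0)
        model = train_backend(kind, x, codes=y, seed=0)
        xq = rng.normal(2, 3, (80, x.shape[1]))
        probs = predict_proba(model, xq)
        soft = np.asarray(model.classes)[probs.argmax(axis=1)]
        xs = model.scaler.transform(xq) if model.scaler is not None else xq
        hard = model.estimator.predict(xs)
        # ties in vote fractions may break differently; demand near-total agreement
        assert (soft == hard).mean() >= 0.99

    def test_svm_argmax_mostly_matches_decision_vote(self, rng):
        # Platt-coupled probabilities are not guaranteed to rank identically
        # to the pairwise decision-function vote; agreement is high but not 1
        x, y = _blobs(rng, n_per_class=40, sep=2.0)
        model = train_backend("svm", x, codes=y, seed=0)
        xq = rng.normal(2, 3, (300, x.shape[1]))
        probs = predict_proba(model, xq)
        soft = np.asarray(model.classes)[probs.argmax(axis=1)]
        hard = model.estimator.predict(model.scaler.transform(xq))
        assert (soft == hard).mean() >= 0.9

    def test_rf_probability_is_vote_fraction(self, rng):
        x, y = _blobs(rng, n_per_class=40, sep=1.0)
        model = train_backend(kind="rf", train_samples=x, codes=y,
                              hyperparams={"n_estimators": 100}, seed=0)
        xq = rng.normal(1, 2, (20, x.shape[1]))
        probs = predict_proba(model, xq)
        votes = np.zeros_like(probs)
        for tree in model.estimator.estimators_:
            leaf = tree.predict(xq.astype(np.float32))  # encoded 0-based indices
            for j in range(len(model.estimator.classes_)):
                votes[:, j] += leaf == j
        np.testing.assert_allclose(probs, votes / 100.0, atol=1e-9)

    def test_wknn_unanimous_neighbours_give_probability_one(self, rng):
        x = np.vstack([np.zeros((12, 3)), np.full((12, 3), 10.0)])
        y = np.repeat([1, 2], 12)
        model = train_backend("wknn", x, codes=y, seed=0)
        probs = predict_proba(model, np.full((1, 3), 0.1))
        assert probs[0, 0] == pytest.approx(1.0)

    def test_wknn_k_truncated_with_warning(self):
        x = np.arange(12, dtype=float).reshape(6, 2)
        y = np.array([1, 1, 2, 2, 3, 3])
        with pytest.warns(UserWarning, match="truncated"):
            model = train_backend("wknn", x, codes=y, seed=0)
        assert model.hyperparams["n_neighbors"] == 6

    def test_nb_zero_variance_feature_gives_finite_probs(self, rng):
        x, y = _blobs(rng, n_per_class=20)
        x[:, 0] = 1.0  # zero variance everywhere
        with pytest.warns(UserWarning, match="zero variance"):
            model = train_backend("nb", x, codes=y, seed=0)
        probs = predict_proba(model, x)
        assert np.isfinite(probs).all()

    @pytest.mark.parametrize("kind", ["rf", "wknn", "nb"])
    def test_refit_is_bitwise_reproducible(self, kind, rng):
        x, y = _blobs(rng)
        xq = rng.normal(3, 4, (30, x.shape[1]))
        p1 = predict_proba(train_backend(kind, x, codes=y, seed=5), xq)
        p2 = predict_proba(train_backend(kind, x, codes=y, seed=5), xq)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("kind", ["ann", "svm"])
    def test_refit_reproducible_within_tolerance(self, kind, rng):
        x, y = _blobs(rng)
        xq = rng.normal(3, 4, (30, x.shape[1]))
        p1 = predict_proba(train_backend(kind, x, codes=y, seed=5), xq)
        p2 = predict_proba(train_backend(kind, x, codes=y, seed=5), xq)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_feature_name_mismatch_listed(self, rng):
        x, y = _blobs(rng, n_per_class=20)
        names = tuple(f"v{i}" for i in range(x.shape[1]))
        model = train_backend("rf", FeatureTable(x, names), codes=y, seed=0)
        wrong = FeatureTable(x, ("v0", "v1", "v2", "v3", "other"))
        with pytest.raises(ValueError, match="missing.*v4.*extra.*other"):
            predict_proba(model, wrong)

    def test_feature_order_insensitive(self, rng):
        x, y = _blobs(rng, n_per_class=20)
        names = tuple(f"v{i}" for i in range(x.shape[1]))
        model = train_backend("rf", FeatureTable(x, names), codes=y, seed=0)
        shuffled = FeatureTable(x[:, ::-1], names[::-1])
        p1 = predict_proba(model, FeatureTable(x, names))
        p2 = predict_proba(model, shuffled)
        np.testing.assert_array_equal(p1, p2)

    def test_missing_class_rejected_when_scheme_given(self, rng):
        scheme = ClassScheme(classes=((1, "A"), (2, "B"), (3, "C"), (4, "D")))
        x, y = _blobs(rng, n_classes=3)
        with pytest.raises(ValueError, match="lacks classes"):
            train_backend("rf", x, codes=y, scheme=scheme, seed=0)

    def test_save_load_round_trip(self, tmp_path, rng):
        x, y = _blobs(rng, n_per_class=20)
        model = train_backend("svm", x, codes=y, seed=0)
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        xq = rng.normal(0, 3, (10, x.shape[1]))
        np.testing.assert_array_equal(
            predict_proba(model, xq), predict_proba(back, xq)
        )


class TestTuning:
    def test_single_point_grid_returned(self, rng):
        x, y = _blobs(rng, n_per_class=20)
        best = tune_hyperparameters(
            "rf", x, {"n_estimators": [37]}, codes=y, folds=2, seed=0
        )
        assert best == {"n_estimators": 37}

    def test_too_many_folds_rejected(self, rng):
        x, y = _blobs(rng, n_per_class=4)
        with pytest.raises(ValueError, match="folds"):
            tune_hyperparameters(
                "rf", x, {"n_estimators": [10]}, codes=y, folds=10, seed=0
            )

    def test_more_trees_win_on_noisy_data(self, rng):
        # repeated-run check at reduced scale: more trees should usually win
        wins = 0
        reps = 10
        for s in range(reps):
            r = np.random.default_rng(s)
            x = r.normal(0, 1, (90, 8))
            y = (x[:, :4].sum(axis=1) + r.normal(0, 2.0, 90) > 0).astype(int) + 1
            if len(np.unique(y)) < 2 or np.bincount(y)[1:].min() < 4:
                continue
            best = tune_hyperparameters(
                "rf", x, {"n_estimators": [5, 150]}, codes=y, folds=3, seed=s
            )
            wins += best["n_estimators"] == 150
            reps_done = s + 1
        assert wins >= 7


def test_triangular_weights_properties(rng):
    d = np.sort(rng.random((10, 7)), axis=1)
    w = triangular_weights(d)
    assert (w > 0).all() and (w <= 1.0).all()
    # weights decrease with distance within each row
    assert np.all(np.diff(w, axis=1) <= 1e-12)


def test_default_hyperparameters_cover_all_kinds():
    for kind in KINDS:
        hp = default_hyperparameters(kind, 44)
        assert isinstance(hp, dict) and hp
    with pytest.raises(ValueError, match="unknown"):
        default_hyperparameters("boost", 44)
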