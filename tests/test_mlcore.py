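"""Splits, balanced replicates, thresholding, selection, ensembles."""

import numpy as np
import pandas as pd
import pytest

from redpred import mlcore
from redpred.mlcore import (
    SelectionConfig,
    balanced_replicates,
    cross_definition_split,
    evaluate,
    evaluate_cv,
    f1_maximizing_threshold,
    feature_importance,
    grid_search_cv,
    predict_scores,
    select_features,
    split_holdout,
    train_ensemble,
)


def make_labels(n_pos, n_neg):
    idx = pd.Index([f"p{i}" for i in range(n_pos + n_neg)])
    return pd.Series([True] * n_pos + [False] * n_neg, index=idx)


def separable_data(n_pos=30, n_neg=30, n_features=6, n_noise=4, seed=0):
    rng = np.random.default_rng(seed)
    y = make_labels(n_pos, n_neg)
    X = rng.normal(size=(n_pos + n_neg, n_features + n_noise))
    X[: n_pos, :n_features] += 4.0  # wide separation on informative columns
    cols = [f"f{i}" for i in range(n_features + n_noise)]
    return pd.DataFrame(X, index=y.index, columns=cols), y


# ---------------------------------------------------------------------------
# splits


def test_holdout_split_stratified_190_110():
    labels = make_labels(190, 110)
    train, test = split_holdout(labels, fraction=0.1, seed=0)
    assert labels.loc[test].sum() == 19
    assert (~labels.loc[test]).sum() == 11
    assert len(train) + len(test) == 300
    assert train.intersection(test).empty


def test_holdout_fraction_zero_and_determinism():
    labels = make_labels(20, 10)
    _, test = split_holdout(labels, fraction=0, seed=0)
    assert len(test) == 0
    a = split_holdout(labels, 0.2, seed=5)
    b = split_holdout(labels, 0.2, seed=5)
    assert a[0].equals(b[0]) and a[1].equals(b[1])
    c = split_holdout(labels, 0.2, seed=6)
    assert not a[1].equals(c[1])


def test_holdout_split_requires_stratifiable_classes():
    with pytest.raises(ValueError):
        split_holdout(make_labels(1, 30), 0.1, seed=0)


def test_balanced_replicates_downsample_majority():
    labels = make_labels(50, 100)
    reps = balanced_replicates(labels, n_replicates=20, seed=0)
    assert len(reps) == 20
    for idx in reps:
        sub = labels.loc[idx]
        assert sub.sum() == 50 and (~sub).sum() == 50
        assert not idx.duplicated().any()
    # replicates differ
    assert len({tuple(sorted(idx)) for idx in reps}) > 1


def test_balanced_replicates_already_balanced():
    labels = make_labels(10, 10)
    reps = balanced_replicates(labels, n_replicates=5, seed=0)
    for idx in reps:
        assert set(idx) == set(labels.index)


# ---------------------------------------------------------------------------
# threshold selection


def test_threshold_worked_example():
    thr, f1 = f1_maximizing_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert thr == 0.8 and f1 == 1.0


def test_threshold_single_candidate():
    thr, f1 = f1_maximizing_threshold([0.5] * 4, [1, 0, 1, 0])
    assert thr == 0.5
    assert f1 == pytest.approx(2 * 2 / (2 * 2 + 2 + 0))  # all-positive call


def test_threshold_optimal_against_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(5, 60))
        scores = rng.random(n)
        labels = rng.random(n) < 0.5
        if labels.sum() == 0:
            labels[0] = True
        thr, f1 = f1_maximizing_threshold(scores, labels)
        for cand in np.unique(scores):
            calls = scores >= cand
            tp = np.sum(calls & labels)
            denom = 2 * tp + np.sum(calls & ~labels) + np.sum(~calls & labels)
            f1_cand = 2 * tp / denom if denom else 0.0
            assert f1 >= f1_cand - 1e-12
            if f1_cand == pytest.approx(f1):
                assert thr <= cand  # ties resolve to the lowest threshold


# ---------------------------------------------------------------------------
# grid search and feature selection


def test_grid_search_single_point_and_determinism():
    X, y = separable_data()
    reps = balanced_replicates(y, 3, seed=0)
    assert grid_search_cv(X, y, "svm", reps, grid={"C": [0.5]}, folds=3) == {"C": 0.5}
    a = grid_search_cv(X, y, "svm", reps, grid={"C": [0.01, 1.0]}, folds=3, seed=1)
    b = grid_search_cv(X, y, "svm", reps, grid={"C": [0.01, 1.0]}, folds=3, seed=1)
    assert a == b


def test_grid_search_picks_candidate_with_best_mean_cv_auc():
    X, y = separable_data(seed=2)
    reps = balanced_replicates(y, 3, seed=2)
    grid = {"C": [1e-4, 1.0]}
    best = grid_search_cv(X, y, "svm", reps, grid=grid, folds=3, seed=0)

    def mean_auc(c):
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        scores = []
        for i, idx in enumerate(reps[:10]):
            est = mlcore._pipeline("svm", {"C": c}, 0 + i, probability=False)
            cv = StratifiedKFold(3, shuffle=True, random_state=0 + i)
            scores.append(
                cross_val_score(
                    est, X.loc[idx], y.loc[idx].astype(int), cv=cv, scoring="roc_auc"
                ).mean()
            )
        return np.mean(scores)

    assert mean_auc(best["C"]) >= mean_auc(
        [c for c in grid["C"] if c != best["C"]][0]
    )


def test_grid_search_rejects_empty_grid():
    X, y = separable_data()
    with pytest.raises(ValueError):
        grid_search_cv(X, y, "svm", balanced_replicates(y, 2), grid={"C": []})


def simple_metadata(columns):
    return pd.DataFrame(
        {
            "base": [c.split("__")[0] for c in columns],
            "aggregation": ["avg"] * len(columns),
            "transform": [
                c.split("__")[-1] if "__" in c else "identity" for c in columns
            ],
        },
        index=pd.Index(columns, name="column"),
    )


def test_select_features_planted_signal_ranked_first():
    rng = np.random.default_rng(0)
    n = 120
    y = make_labels(60, 60)
    X = pd.DataFrame(
        rng.normal(size=(n, 30)),
        index=y.index,
        columns=[f"noise{i}" for i in range(30)],
    )
    X["planted"] = rng.normal(size=n) + 2.0 * y.to_numpy()
    meta = simple_metadata(list(X.columns))
    reps = balanced_replicates(y, 5, seed=0)
    config = SelectionConfig(method="random_forest", k=5, scheme="MT")
    selected = select_features(X, y, meta, config, reps, seed=0)
    assert selected[0] == "planted"
    assert len(selected) == 5


def test_select_features_elastic_net_and_nt_scheme():
    rng = np.random.default_rng(1)
    y = make_labels(40, 40)
    X = pd.DataFrame(
        rng.normal(size=(80, 10)),
        index=y.index,
        columns=[f"f{i}" for i in range(5)] + [f"f{i}__square" for i in range(5)],
    )
    X["f0"] += 2.0 * y.to_numpy()
    meta = simple_metadata(list(X.columns))
    reps = balanced_replicates(y, 3, seed=1)
    selected = select_features(
        X, y, meta, SelectionConfig("elastic_net", k=3, scheme="NT"), reps
    )
    assert len(selected) == 3
    assert all("__square" not in c for c in selected)  # NT: untransformed only
    assert selected[0] == "f0"


def test_select_features_bt_one_variant_per_base_aggregation():
    rng = np.random.default_rng(2)
    y = make_labels(30, 30)
    cols = ["a__avg", "a__avg__square", "a__avg__log10", "b__avg", "b__avg__square"]
    X = pd.DataFrame(rng.normal(size=(60, 5)), index=y.index, columns=cols)
    meta = pd.DataFrame(
        {
            "base": ["a", "a", "a", "b", "b"],
            "aggregation": ["avg"] * 5,
            "transform": ["identity", "square", "log10", "identity", "square"],
        },
        index=pd.Index(cols, name="column"),
    )
    reps = balanced_replicates(y, 2, seed=0)
    selected = select_features(
        X, y, meta, SelectionConfig("random_forest", k=2, scheme="BT"), reps
    )
    bases = [meta.loc[c, "base"] for c in selected]
    assert len(bases) == len(set(bases)) == 2


def test_select_features_k_too_large():
    X, y = separable_data()
    meta = simple_metadata(list(X.columns))
    with pytest.raises(ValueError, match="available"):
        select_features(
            X, y, meta, SelectionConfig(k=999), balanced_replicates(y, 2)
        )


# ---------------------------------------------------------------------------
# ensemble training / evaluation


@pytest.fixture(scope="module")
def toy_ensemble():
    X, y = separable_data(n_pos=40, n_neg=60, seed=4)
    ensemble = train_ensemble(
        X, y, "svm", {"C": 1.0}, list(X.columns), n_replicates=5, folds=4, seed=0
    )
    return X, y, ensemble


def test_ensemble_structure_and_thresholds(toy_ensemble):
    X, y, ensemble = toy_ensemble
    assert ensemble.n_replicates == 5
    for m in ensemble.members:
        assert 0.0 < m.threshold < 1.0
        assert set(m.features) <= set(ensemble.selected_features)
        # the stored threshold is optimal for the stored out-of-fold scores
        thr, f1 = f1_maximizing_threshold(m.oof_scores, m.oof_labels)
        assert (thr, f1) == (m.threshold, m.f1_at_threshold)


def test_evaluate_separable_data(toy_ensemble):
    X, y, ensemble = toy_ensemble
    summary = evaluate_cv(ensemble)
    assert summary.auc_roc > 0.99
    assert summary.au_prc > 0.99
    ext = evaluate(ensemble, X, y)
    assert ext.auc_roc > 0.99
    assert ext.confusion.sum() == len(y)


def test_predict_scores_bounded_by_member_range(toy_ensemble):
    X, y, ensemble = toy_ensemble
    preds = predict_scores(ensemble, X)
    member_scores = np.vstack(
        [mlcore._member_scores(m, X) for m in ensemble.members]
    )
    assert (preds["score"] >= member_scores.min(axis=0) - 1e-12).all()
    assert (preds["score"] <= member_scores.max(axis=0) + 1e-12).all()
    assert ((preds["score"] >= 0) & (preds["score"] <= 1)).all()
    # positive training instances of separable data score above threshold
    assert preds.loc[y, "call"].mean() > 0.9


def test_predict_missing_columns_listed(toy_ensemble):
    X, y, ensemble = toy_ensemble
    with pytest.raises(KeyError, match="f0"):
        predict_scores(ensemble, X.drop(columns=["f0"]))


def test_evaluate_rejects_single_class(toy_ensemble):
    X, y, ensemble = toy_ensemble
    with pytest.raises(ValueError):
        evaluate(ensemble, X.loc[y], y.loc[y])


def test_feature_importance_recovers_informative_columns(toy_ensemble):
    X, y, ensemble = toy_ensemble
    imp = feature_importance(ensemble)
    assert sorted(imp["rank"]) == list(range(1, len(imp) + 1))
    # informative columns f0..f5 dominate noise columns
    top6 = set(imp.index[:6])
    assert top6 == {f"f{i}" for i in range(6)}


def test_ensemble_training_deterministic():
    X, y = separable_data(seed=9)
    kw = dict(n_replicates=3, folds=3, seed=42)
    e1 = train_ensemble(X, y, "svm", {"C": 1.0}, list(X.columns), **kw)
    e2 = train_ensemble(X, y, "svm", {"C": 1.0}, list(X.columns), **kw)
    assert [m.threshold for m in e1.members] == [m.threshold for m in e2.members]
    np.testing.assert_array_equal(
        predict_scores(e1, X)["score"], predict_scores(e2, X)["score"]
    )


def test_label_permutation_auc_near_half():
    rng = np.random.default_rng(0)
    aucs = []
    for seed in range(3):
        X, y = separable_data(n_pos=50, n_neg=50, seed=seed)
        permuted = pd.Series(
            rng.permutation(y.to_numpy()), index=y.index
        )
        ensemble = train_ensemble(
            X, permuted, "svm", {"C": 1.0}, list(X.columns),
            n_replicates=4, folds=4, seed=seed,
        )
        aucs.append(evaluate_cv(ensemble).auc_roc)
    assert 0.35 < np.mean(aucs) < 0.65


def test_tree_algorithms_importances():
    X, y = separable_data(n_pos=25, n_neg=25, seed=3)
    ensemble = train_ensemble(
        X, y, "random_forest", {"n_estimators": 50}, list(X.columns),
        n_replicates=2, folds=3, seed=0,
    )
    imp = feature_importance(ensemble)
    assert imp["importance"].sum() > 0
    assert evaluate_cv(ensemble).auc_roc > 0.9


# ---------------------------------------------------------------------------
# cross-definition protocol


def labels_frame():
    idx = pd.Index([f"p{i}" for i in range(100)])
    rd4 = np.zeros(100, bool)
    rd4[:20] = True
    rd9 = np.zeros(100, bool)
    rd9[:60] = True  # RD4 subset of RD9
    nr = ~rd9
    return pd.DataFrame({"RD4": rd4, "RD9": rd9, "NR": nr}, index=idx)


def test_cross_definition_split_disjoint_and_composed():
    df = labels_frame()
    train, test = cross_definition_split(df, "RD4", "RD9", seed=0)
    assert train.index.intersection(test.index).empty
    assert train.sum() == 20          # RD4 redundant pairs
    assert test.sum() == 40           # RD9 minus RD4
    assert (~train).sum() == 20 and (~test).sum() == 20  # NR halves
    assert set(train.index[~train]) | set(test.index[~test]) == set(
        df.index[df["NR"]]
    )


def test_cross_definition_same_definition_rejected():
    with pytest.raises(ValueError, match="empty"):
        cross_definition_split(labels_frame(), "RD9", "RD9", seed=0)
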