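"""Balanced-ensemble classifier machinery for redundancy prediction.

The protocol: hold out 10% of the benchmark (stratified), down-sample the
majority class to the minority-class size 100 times to form balanced
replicates, pick hyperparameters by 10-fold cross-validation over the first
ten replicates, select features (random-forest importance or elastic net,
under the NT/MT/BT transformation schemes), then fit one classifier per
replicate.  Each member min-max scales its features within training folds,
scores its replicate out-of-fold, and fixes the decision threshold at the
value maximizing F1 over the out-of-fold score candidates.  The ensemble's
redundancy score for a pair is the mean calibrated member probability; the
binary call compares it with the mean member threshold.

Linear-kernel SVM members expose |weight|-based feature importances; tree
ensembles use impurity importances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import ElasticNetCV
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import (
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

ALGORITHMS = ("svm", "random_forest", "gradient_boosting")

#: candidate lists ordered from least to most complex (ties in mean CV AUC
#: resolve toward the earlier, simpler grid point)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0]},
    "random_forest": {
        "n_estimators": [100, 500],
        "max_depth": [3, 5, 10, None],
        "max_features": ["sqrt", 0.1, 0.5],
    },
    "gradient_boosting": {
        "learning_rate": [0.01, 0.1, 0.3],
        "max_depth": [3, 5, 10],
        "max_features": ["sqrt", 0.1, 0.5],
    },
}


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def make_estimator(algorithm: str, params: dict, seed: int, probability: bool = True):
    """Bare classifier for one ensemble member (scaling is added separately).

    Linear-SVM decision values are mapped to [0, 1] likelihood scores by
    Platt-style sigmoid calibration fitted on internal folds.
    """
    if algorithm == "svm":
        svc = SVC(kernel="linear", random_state=seed, **params)
        if not probability:
            return svc
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def _pipeline(algorithm: str, params: dict, seed: int, probability: bool = True) -> Pipeline:
    return Pipeline(
        [
            ("scale", MinMaxScaler()),
            ("model", make_estimator(algorithm, params, seed, probability)),
        ]
    )


# ---------------------------------------------------------------------------
# splits and resampling


def split_holdout(
    labels: pd.Series, fraction: float = 0.1, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Stratified holdout split; returns (train_ids, test_ids)."""
    if fraction == 0:
        return labels.index, labels.index[:0]
    y = labels.astype(int)
    if y.value_counts().min() < 2:
        raise ValueError("each class needs >=2 instances to stratify the holdout")
    train, test = train_test_split(
        labels.index, test_size=fraction, stratify=y, random_state=seed
    )
    return pd.Index(train), pd.Index(test)


def balanced_replicates(
    labels: pd.Series, n_replicates: int = 100, seed: int = 0
) -> list[pd.Index]:
    """Down-sample the majority class to the minority size, ``n_replicates`` times.

    Minority instances are always all retained; majority instances are drawn
    without replacement with a distinct sub-seed per replicate.
    """
    y = labels.astype(bool)
    pos = labels.index[y]
    neg = labels.index[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        if len(minority) == len(majority):
            sampled = majority
        else:
            sampled = pd.Index(
                rng.choice(majority, size=len(minority), replace=False)
            )
        out.append(minority.append(pd.Index(sampled)))
    return out


# ---------------------------------------------------------------------------
# hyperparameters and feature selection


def grid_search_cv(
    X: pd.DataFrame,
    y: pd.Series,
    algorithm: str,
    balanced_sets: Sequence[pd.Index],
    grid: dict[str, list] | None = None,
    folds: int = 10,
    n_balanced: int = 10,
    seed: int = 0,
) -> dict:
    """Pick the grid point with the best mean CV AUC-ROC.

    Evaluated with ``folds``-fold stratified CV on each of the first
    ``n_balanced`` balanced replicates; ties go to the earlier (simpler) grid
    point since candidate lists are ordered by complexity.
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    names = list(grid)
    points = [dict(zip(names, combo)) for combo in product(*(grid[n] for n in names))]
    use_sets = list(balanced_sets)[:n_balanced]
    best_params, best_score = None, -np.inf
    for params in points:
        scores = []
        for i, idx in enumerate(use_sets):
            est = _pipeline(algorithm, params, seed + i, probability=False)
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + i)
            scores.append(
                cross_val_score(
                    est, X.loc[idx], y.loc[idx].astype(int), cv=cv, scoring="roc_auc"
                ).mean()
            )
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_params, best_score = params, mean_score
    return best_params


@dataclass
class SelectionConfig:
    """How to choose the feature subset fed to the ensemble."""

    method: str = "random_forest"    # or "elastic_net"
    k: int = 200
    scheme: str = "BT"               # NT | MT | BT
    n_ranking_replicates: int = 10
    rf_trees: int = 100

    def __post_init__(self) -> None:
        if self.method not in ("random_forest", "elastic_net"):
            raise ValueError(f"unknown selection method {self.method!r}")
        if self.scheme not in ("NT", "MT", "BT"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def _ranking_scores(
    X: pd.DataFrame,
    y: pd.Series,
    config: SelectionConfig,
    balanced_sets: Sequence[pd.Index],
    seed: int,
) -> pd.Series:
    if config.method == "random_forest":
        total = np.zeros(X.shape[1])
        use_sets = list(balanced_sets)[: config.n_ranking_replicates]
        for i, idx in enumerate(use_sets):
            rf = RandomForestClassifier(
                n_estimators=config.rf_trees, random_state=seed + i
            )
            rf.fit(X.loc[idx], y.loc[idx].astype(int))
            total += rf.feature_importances_
        return pd.Series(total / len(use_sets), index=X.columns)
    # elastic net: |coefficient| at the cross-validated penalty, on min-max
    # scaled features against the 0/1 label
    scaled = MinMaxScaler().fit_transform(X)
    en = ElasticNetCV(l1_ratio=0.5, cv=5, random_state=seed)
    en.fit(scaled, y.astype(float))
    return pd.Series(np.abs(en.coef_), index=X.columns)


def select_features(
    X: pd.DataFrame,
    y: pd.Series,
    metadata: pd.DataFrame,
    config: SelectionConfig,
    balanced_sets: Sequence[pd.Index],
    seed: int = 0,
    clamp: bool = False,
) -> list[str]:
    """Ordered top-k feature list under the configured method and scheme.

    NT restricts candidates to untransformed columns; MT keeps every variant;
    BT first collapses each base feature to its single highest-scoring variant
    ("best transformation") before taking the top k.
    """
    if config.scheme == "NT":
        candidates = [
            c for c in X.columns if metadata.loc[c, "transform"] == "identity"
        ]
    else:
        candidates = list(X.columns)
    scores = _ranking_scores(X[candidates], y, config, balanced_sets, seed)
    ordered = scores.sort_values(ascending=False, kind="mergesort")
    if config.scheme == "BT":
        # "best transformation": keep one variant per aggregated base feature
        # (base x aggregation), so e.g. max-Ks and min-Ks stay distinct
        best_per_base: dict[tuple[str, str], str] = {}
        for col in ordered.index:  # descending score: first hit per base wins
            base = (metadata.loc[col, "base"], metadata.loc[col, "aggregation"])
            best_per_base.setdefault(base, col)
        ordered = ordered.loc[list(best_per_base.values())]
        ordered = ordered.sort_values(ascending=False, kind="mergesort")
    if config.k > len(ordered):
        if not clamp:
            raise ValueError(
                f"k={config.k} features requested but only {len(ordered)} "
                f"available under scheme {config.scheme}"
            )
        return list(ordered.index)
    return list(ordered.index[: config.k])


# ---------------------------------------------------------------------------
# threshold selection


def f1_maximizing_threshold(scores, labels) -> tuple[float, float]:
    """Threshold (over the sorted unique scores) maximizing F1; ties -> lowest.

    Calls are positive when score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    candidates = np.unique(scores)
    ge = scores[None, :] >= candidates[:, None]
    tp = (ge & labels[None, :]).sum(axis=1)
    fp = (ge & ~labels[None, :]).sum(axis=1)
    fn = labels.sum() - tp
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    best = np.argmax(f1)  # argmax takes the first (lowest) threshold on ties
    return float(candidates[best]), float(f1[best])


# ---------------------------------------------------------------------------
# the ensemble


@dataclass
class EnsembleMember:
    pipeline: Pipeline
    features: list[str]
    threshold: float
    f1_at_threshold: float
    sampled_ids: pd.Index
    oof_scores: np.ndarray
    oof_labels: np.ndarray


@dataclass
class ModelEnsemble:
    members: list[EnsembleMember]
    algorithm: str
    hyperparams: dict
    selected_features: list[str]
    seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.members)

    @property
    def threshold(self) -> float:
        return float(np.mean([m.threshold for m in self.members]))


def train_ensemble(
    X: pd.DataFrame,
    y: pd.Series,
    algorithm: str,
    hyperparams: dict,
    selected_features: Sequence[str],
    n_replicates: int = 100,
    folds: int = 10,
    seed: int = 0,
    balanced_sets: Sequence[pd.Index] | None = None,
) -> ModelEnsemble:
    """Fit one classifier per balanced replicate with out-of-fold thresholds.

    Per member: min-max scaling is fit inside each CV training fold (and on the
    whole replicate for the final refit), out-of-fold probability scores feed
    the F1-maximizing threshold, and zero-variance features are dropped for
    that member only.
    """
    selected_features = list(selected_features)
    missing = [f for f in selected_features if f not in X.columns]
    if missing:
        raise KeyError(f"selected features absent from the matrix: {missing}")
    if balanced_sets is None:
        balanced_sets = balanced_replicates(y, n_replicates, seed)
    rng = np.random.default_rng(seed)
    members: list[EnsembleMember] = []
    for idx in balanced_sets[:n_replicates]:
        member_seed = _sub_seed(rng)
        Xr = X.loc[idx, selected_features]
        yr = y.loc[idx].astype(int).to_numpy()
        variances = Xr.var(axis=0)
        feats = list(variances.index[variances > 0])
        dropped = sorted(set(selected_features) - set(feats))
        if dropped:
            logger.info("member dropped zero-variance features: %s", dropped)
        est = _pipeline(algorithm, hyperparams, member_seed)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=member_seed)
        oof = cross_val_predict(
            est, Xr[feats], yr, cv=cv, method="predict_proba"
        )[:, 1]
        threshold, f1 = f1_maximizing_threshold(oof, yr)
        est.fit(Xr[feats], yr)
        members.append(
            EnsembleMember(
                pipeline=est,
                features=feats,
                threshold=threshold,
                f1_at_threshold=f1,
                sampled_ids=idx,
                oof_scores=oof,
                oof_labels=yr.astype(bool),
            )
        )
    return ModelEnsemble(
        members=members,
        algorithm=algorithm,
        hyperparams=dict(hyperparams),
        selected_features=selected_features,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationSummary:
    """Averaged ROC/PR curves and threshold-based classification metrics."""

    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_sd: np.ndarray
    recall_grid: np.ndarray
    precision_mean: np.ndarray
    precision_sd: np.ndarray
    auc_roc: float
    au_prc: float
    threshold: float
    confusion: np.ndarray       # [[TP, FN], [FP, TN]]
    precision: float
    recall: float
    f1: float
    n_instances: int


_GRID = np.linspace(0.0, 1.0, 101)


def _roc_on_grid(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    fpr, tpr, _ = roc_curve(labels.astype(int), scores)
    return np.interp(_GRID, fpr, tpr)


def _pr_on_grid(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    precision, recall, _ = precision_recall_curve(labels.astype(int), scores)
    order = np.argsort(recall)
    return np.interp(_GRID, recall[order], precision[order])


def _summarize(
    per_member_scores: list[np.ndarray],
    per_member_labels: list[np.ndarray],
    threshold: float,
    call_scores: np.ndarray,
    call_labels: np.ndarray,
) -> EvaluationSummary:
    tprs = np.vstack(
        [_roc_on_grid(s, l) for s, l in zip(per_member_scores, per_member_labels)]
    )
    precs = np.vstack(
        [_pr_on_grid(s, l) for s, l in zip(per_member_scores, per_member_labels)]
    )
    tpr_mean, tpr_sd = tprs.mean(axis=0), tprs.std(axis=0)
    prec_mean, prec_sd = precs.mean(axis=0), precs.std(axis=0)
    auc_roc = float(np.trapezoid(tpr_mean, _GRID))
    au_prc = float(np.trapezoid(prec_mean, _GRID))
    calls = call_scores >= threshold
    labels = call_labels.astype(bool)
    tp = int(np.sum(calls & labels))
    fn = int(np.sum(~calls & labels))
    fp = int(np.sum(calls & ~labels))
    tn = int(np.sum(~calls & ~labels))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvaluationSummary(
        fpr_grid=_GRID.copy(),
        tpr_mean=tpr_mean,
        tpr_sd=tpr_sd,
        recall_grid=_GRID.copy(),
        precision_mean=prec_mean,
        precision_sd=prec_sd,
        auc_roc=auc_roc,
        au_prc=au_prc,
        threshold=threshold,
        confusion=np.array([[tp, fn], [fp, tn]]),
        precision=precision,
        recall=recall,
        f1=f1,
        n_instances=len(call_labels),
    )


def evaluate_cv(ensemble: ModelEnsemble) -> EvaluationSummary:
    """Cross-validation performance: curves averaged over the members'
    out-of-fold scores on their own balanced replicates."""
    scores = [m.oof_scores for m in ensemble.members]
    labels = [m.oof_labels for m in ensemble.members]
    for l in labels:
        if l.all() or not l.any():
            raise ValueError("single-class replicate; ROC undefined")
    # pooled calls: each member's out-of-fold scores against its own threshold
    call_scores = np.concatenate(scores)
    call_labels = np.concatenate(labels)
    pooled_threshold = ensemble.threshold
    return _summarize(scores, labels, pooled_threshold, call_scores, call_labels)


def evaluate(ensemble: ModelEnsemble, X: pd.DataFrame, y: pd.Series) -> EvaluationSummary:
    """Performance on labeled external data (e.g. the holdout set)."""
    labels = y.astype(bool).to_numpy()
    if labels.all() or not labels.any():
        raise ValueError("evaluation data must contain both classes")
    member_scores = [_member_scores(m, X) for m in ensemble.members]
    mean_scores = np.vstack(member_scores).mean(axis=0)
    return _summarize(
        member_scores,
        [labels] * len(member_scores),
        ensemble.threshold,
        mean_scores,
        labels,
    )


def _member_scores(member: EnsembleMember, X: pd.DataFrame) -> np.ndarray:
    missing = [f for f in member.features if f not in X.columns]
    if missing:
        raise KeyError(f"feature columns missing from input: {missing}")
    return member.pipeline.predict_proba(X[member.features])[:, 1]


def predict_scores(ensemble: ModelEnsemble, X: pd.DataFrame) -> pd.DataFrame:
    """Redundancy scores in [0, 1] (ensemble-mean member probability) and
    binary calls at the ensemble threshold."""
    member_scores = np.vstack([_member_scores(m, X) for m in ensemble.members])
    score = member_scores.mean(axis=0)
    return pd.DataFrame(
        {
            "score": score,
            "call": score >= ensemble.threshold,
            "threshold": ensemble.threshold,
        },
        index=X.index,
    )


def feature_importance(ensemble: ModelEnsemble) -> pd.DataFrame:
    """Mean |SVM weight| (or impurity importance) per feature across members.

    Returns a DataFrame indexed by feature with ``importance`` and ``rank``
    (1 = most important; ties broken by feature name for determinism).
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for m in ensemble.members:
        model = m.pipeline.named_steps["model"]
        if ensemble.algorithm == "svm":
            svc = model.calibrated_classifiers_[0].estimator
            if svc.kernel != "linear":
                raise ValueError(
                    "weight-based importance needs a linear kernel; use "
                    "permutation importance for nonlinear kernels"
                )
            weights = np.abs(svc.coef_.ravel())
        else:
            weights = model.feature_importances_
        for f, w in zip(m.features, weights):
            sums[f] = sums.get(f, 0.0) + float(w)
            counts[f] = counts.get(f, 0) + 1
    df = pd.DataFrame(
        {"importance": {f: sums[f] / counts[f] for f in sums}}
    ).rename_axis("feature")
    df = df.iloc[np.lexsort((df.index, -df["importance"].to_numpy()))]
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# cross-definition protocol


def cross_definition_split(
    labels_df: pd.DataFrame, train_def: str, test_def: str, seed: int = 0
) -> tuple[pd.Series, pd.Series]:
    """Train/test composition for training under one definition and testing
    under another.

    The training set is the ``train_def`` redundant pairs plus a random half of
    the nonredundant pool; the test set is the other half of the nonredundant
    pool plus the ``test_def`` redundant pairs not already used for training.
    Returns (train_labels, test_labels) as boolean Series; the index sets are
    disjoint by construction (asserted).
    """
    red_train = labels_df.index[labels_df[train_def]]
    red_test = labels_df.index[labels_df[test_def] & ~labels_df[train_def]]
    if len(red_test) == 0:
        raise ValueError(
            f"no {test_def} redundant pairs outside {train_def}; "
            "cross-definition test set is empty"
        )
    nr = labels_df.index[labels_df["NR"]].to_numpy()
    rng = np.random.default_rng(seed)
    rng.shuffle(nr)
    half = len(nr) // 2
    nr_train, nr_test = pd.Index(nr[:half]), pd.Index(nr[half:])
    train_labels = pd.Series(
        np.concatenate([np.ones(len(red_train), bool), np.zeros(len(nr_train), bool)]),
        index=red_train.append(nr_train),
    )
    test_labels = pd.Series(
        np.concatenate([np.ones(len(red_test), bool), np.zeros(len(nr_test), bool)]),
        index=red_test.append(nr_test),
    )
    overlap = train_labels.index.intersection(test_labels.index)
    assert overlap.empty, f"train/test overlap: {list(overlap)}"
    return train_labels, test_labels


def cross_definition_protocol(
    X: pd.DataFrame,
    labels_df: pd.DataFrame,
    train_def: str,
    test_def: str,
    algorithm: str = "svm",
    hyperparams: dict | None = None,
    selected_features: Sequence[str] | None = None,
    n_replicates: int = 100,
    folds: int = 10,
    seed: int = 0,
) -> EvaluationSummary:
    """Train under ``train_def``, evaluate on the ``test_def`` composition."""
    train_labels, test_labels = cross_definition_split(
        labels_df, train_def, test_def, seed
    )
    hyperparams = hyperparams or {"C": 1.0} if algorithm == "svm" else (hyperparams or {})
    features = list(selected_features) if selected_features is not None else list(X.columns)
    ensemble = train_ensemble(
        X.loc[train_labels.index],
        train_labels,
        algorithm,
        hyperparams,
        features,
        n_replicates=n_replicates,
        folds=folds,
        seed=seed,
    )
    return evaluate(ensemble, X.loc[test_labels.index], test_labels)
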