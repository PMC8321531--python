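"""Misprediction diagnostics.

Two views of why nonredundant pairs get called redundant: (1) per-feature
separation scores locating the mispredicted nonredundant pairs between the
correctly predicted nonredundant and redundant groups, flagged when a feature
both separates strongly (score near 1) and carries high model importance; and
(2) a PCA over the correctly and incorrectly predicted nonredundant pairs,
reporting per-dimension explained variance and the features loading most
heavily on the first dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import stats as rstats
from .pairfeat import PairFeatureMatrix


@dataclass
class MispredictionReport:
    per_feature: pd.DataFrame           # separation_score, importance_rank, flagged
    pca_explained: np.ndarray           # explained-variance fractions, non-increasing
    pca_loadings: pd.DataFrame          # features x dimensions
    top_dim1: pd.DataFrame              # top contributors to Dimension 1, by |loading|
    fraction_score_one: float           # descriptive: share of features at exactly 1
    empty: bool = False
    reason: str = ""


def _empty_report(reason: str) -> MispredictionReport:
    return MispredictionReport(
        per_feature=pd.DataFrame(
            columns=["separation_score", "importance_rank", "flagged"]
        ),
        pca_explained=np.array([]),
        pca_loadings=pd.DataFrame(),
        top_dim1=pd.DataFrame(columns=["dimension", "feature", "loading"]),
        fraction_score_one=np.nan,
        empty=True,
        reason=reason,
    )


def misprediction_report(
    matrix: PairFeatureMatrix | pd.DataFrame,
    actual: pd.Series,
    predicted: pd.Series,
    importances: pd.DataFrame,
    score_threshold: float = 0.9,
    rank_threshold: int = 10,
    n_components: int | None = None,
    top_contributors: int = 24,
) -> MispredictionReport:
    """Diagnose which features drive nonredundant-pair mispredictions.

    ``actual``/``predicted`` are boolean (True = redundant), indexed like the
    matrix rows; ``importances`` must carry a ``rank`` column (1 = best).  A
    feature is flagged when its separation score >= ``score_threshold`` and its
    importance rank <= ``rank_threshold``.  The PCA input is the z-scored
    feature matrix of all actually-nonredundant pairs.
    """
    values = matrix.values if isinstance(matrix, PairFeatureMatrix) else matrix
    actual = actual.reindex(values.index).astype(bool)
    predicted = predicted.reindex(values.index).astype(bool)
    mispredicted_nr = (~actual) & predicted
    if not mispredicted_nr.any():
        return _empty_report("no mispredicted nonredundant pairs")

    rows = {}
    for col in values.columns:
        try:
            score = rstats.separation_score(
                values[col].to_numpy(float), actual.to_numpy(), predicted.to_numpy()
            )
        except ValueError:
            score = np.nan
        rank = (
            int(importances.loc[col, "rank"]) if col in importances.index else np.nan
        )
        flagged = (
            np.isfinite(score)
            and score >= score_threshold
            and not np.isnan(rank)
            and rank <= rank_threshold
        )
        rows[col] = {
            "separation_score": score,
            "importance_rank": rank,
            "flagged": bool(flagged),
        }
    per_feature = pd.DataFrame.from_dict(rows, orient="index").rename_axis("feature")
    finite = per_feature["separation_score"].dropna()
    fraction_one = float((finite == 1.0).mean()) if len(finite) else np.nan

    # PCA of correctly vs incorrectly predicted nonredundant pairs
    nr_rows = values.loc[~actual]
    X = nr_rows.to_numpy(float)
    sd = X.std(axis=0)
    keep = sd > 0
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    max_comp = min(Xz.shape) - 1 if min(Xz.shape) > 1 else 1
    k = min(n_components or max_comp, max_comp)
    pca = PCA(n_components=k)
    pca.fit(Xz)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=nr_rows.columns[keep],
        columns=[f"Dim{i + 1}" for i in range(k)],
    )
    dim1 = loadings["Dim1"]
    top = dim1.reindex(dim1.abs().sort_values(ascending=False).index)[
        :top_contributors
    ]
    top_dim1 = pd.DataFrame(
        {"dimension": "Dim1", "feature": top.index, "loading": top.to_numpy()}
    ).reset_index(drop=True)
    return MispredictionReport(
        per_feature=per_feature,
        pca_explained=pca.explained_variance_ratio_,
        pca_loadings=loadings,
        top_dim1=top_dim1,
        fraction_score_one=fraction_one,
    )
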