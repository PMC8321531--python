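"""Feature-class association statistics and cross-definition comparisons.

Binary pair features (counts in {0,1,2}, dichotomized as presence of the
annotation in at least one gene) are tested against the redundancy label with
two-sided Fisher's exact tests; continuous features with Wilcoxon rank-sum
tests.  p-values are corrected with Benjamini-Hochberg; a feature is called
class-distinguishing at q < 0.05 by default.  Effect sizes follow the field's
conventions: odds ratio for binary features and z / sqrt(n) for continuous
features, where z is recovered from the two-sided p-value with the sign of the
location shift.

The feature separation score locates mispredicted nonredundant pairs between
the correctly predicted nonredundant and redundant groups on one feature::

    score = (Med[NR predicted RD] - Med[NR predicted NR])
            / (Med[RD predicted RD] - Med[NR predicted NR])

0 means mispredicted pairs look like correct nonredundant pairs; 1 means they
look like redundant pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .pairfeat import PairFeatureMatrix


@dataclass
class AssocResult:
    feature: str
    test: str               # "fisher" | "wilcoxon"
    p: float
    effect: float           # odds ratio (fisher) or z/sqrt(n) (wilcoxon)
    direction: str          # which class has higher values / odds
    n: int
    q: float = np.nan
    note: str = ""


def fisher_binary(values, labels) -> tuple[float, float]:
    """Two-sided Fisher's exact test of a binary pair feature against the label.

    Pair counts {0,1,2} are dichotomized as presence (>=1) vs absence.  Returns
    (odds_ratio, p).  The odds ratio is the cross-product ratio, with a 0.5
    continuity correction when any cell is zero; a degenerate margin yields
    p = 1 and an undefined (NaN) odds ratio.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    present = values >= 1
    table = np.array(
        [
            [np.sum(present & labels), np.sum(present & ~labels)],
            [np.sum(~present & labels), np.sum(~present & ~labels)],
        ],
        dtype=float,
    )
    return fisher_table(table)


def fisher_table(table) -> tuple[float, float]:
    """Fisher's exact test on an explicit 2x2 count table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("fisher_table expects a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, 1.0
    _, p = sps.fisher_exact(table, alternative="two-sided")
    a, b, c, d = table.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), float(p)


def wilcoxon_continuous(values, labels, method: str = "auto") -> tuple[float, float, float]:
    """Wilcoxon rank-sum test of a continuous feature against the label.

    Returns (p, z, effect) with effect = z / sqrt(n).  z is recovered from the
    two-sided p via the standard normal quantile, signed positive when the
    positive-label class has the higher mean rank.  ``method`` is "exact",
    "asymptotic" (normal approximation with tie correction) or "auto"
    (exact when both groups have <=25 observations and there are no ties).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    x, y = values[labels], values[~labels]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 observations per class")
    if np.all(values == values[0]):
        return 1.0, 0.0, 0.0
    if method == "auto":
        ties = len(np.unique(values)) < len(values)
        method = "exact" if (max(len(x), len(y)) <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    # sign from the mean-rank shift of the positive class
    ranks = sps.rankdata(values)
    sign = 1.0 if ranks[labels].mean() >= ranks[~labels].mean() else -1.0
    z = sign * sps.norm.isf(min(p, 1.0) / 2.0)
    if not math.isfinite(z):
        z = sign * 38.0  # p underflow; beyond double precision of the normal tail
    n = len(values)
    return p, z, z / math.sqrt(n)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (clipped at 1, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def associate_features(
    matrix: PairFeatureMatrix,
    labels: pd.Series,
    wilcoxon_method: str = "asymptotic",
) -> pd.DataFrame:
    """Per-feature association tests over an engineered pair feature matrix.

    Binary base-feature counts (untransformed) get Fisher's exact test; all
    continuous and categorical-summary columns get the Wilcoxon rank-sum test.
    Returns a DataFrame indexed by column with p, q, effect, direction, n.
    """
    labels = labels.reindex(matrix.values.index)
    if labels.isna().any():
        raise ValueError("labels missing for some pairs in the matrix")
    y = labels.to_numpy(bool)
    results: list[AssocResult] = []
    for name in matrix.values.columns:
        meta = matrix.metadata.loc[name]
        vals = matrix.values[name].to_numpy(float)
        if meta["data_type"] == "binary":
            if meta["transform"] != "identity":
                continue  # one Fisher test per binary base feature
            oddsr, p = fisher_binary(vals, y)
            direction = "redundant" if (np.isnan(oddsr) or oddsr >= 1) else "nonredundant"
            results.append(
                AssocResult(name, "fisher", p, oddsr, direction, len(vals))
            )
        else:
            p, z, eff = wilcoxon_continuous(vals, y, method=wilcoxon_method)
            direction = "redundant" if z >= 0 else "nonredundant"
            results.append(AssocResult(name, "wilcoxon", p, eff, direction, len(vals)))
    df = pd.DataFrame([r.__dict__ for r in results]).set_index("feature")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def separation_score(values, actual, predicted) -> float:
    """Feature separation score for mispredicted nonredundant pairs.

    ``actual`` and ``predicted`` are boolean arrays (True = redundant).  The
    three groups - NR predicted NR, NR predicted redundant, redundant predicted
    redundant - must all be non-empty.  Returns NaN when the correct-NR and
    correct-redundant medians coincide (feature uninformative).
    """
    values = np.asarray(values, dtype=float)
    actual = np.asarray(actual, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    groups = {
        "NR predicted NR": values[~actual & ~predicted],
        "NR predicted redundant": values[~actual & predicted],
        "redundant predicted redundant": values[actual & predicted],
    }
    for gname, g in groups.items():
        if g.size == 0:
            raise ValueError(f"group empty: {gname}")
    med_nr = np.median(groups["NR predicted NR"])
    med_mis = np.median(groups["NR predicted redundant"])
    med_rd = np.median(groups["redundant predicted redundant"])
    denom = med_rd - med_nr
    if denom == 0:
        return np.nan
    return float((med_mis - med_nr) / denom)


@dataclass
class DefinitionComparison:
    spearman_rho: float      # of -log10(q) across shared features
    spearman_p: float
    pearson_r: float | None  # of importance ranks (None when not supplied)
    n_shared: int
    n_shared_top_k: int | None
    top_k: int | None


def compare_definitions(
    assoc_a: pd.DataFrame,
    assoc_b: pd.DataFrame,
    importance_a: pd.DataFrame | None = None,
    importance_b: pd.DataFrame | None = None,
    top_k: int = 20,
) -> DefinitionComparison:
    """Agreement of association strength and importance between two definitions.

    Spearman's rank correlation of -log10(q) over the feature intersection, and
    (when importance tables with a ``rank`` column are supplied) Pearson's
    correlation of importance ranks over the shared selected features.
    """
    shared = assoc_a.index.intersection(assoc_b.index)
    if shared.empty:
        raise ValueError("no shared features between the two association tables")
    with np.errstate(divide="ignore"):
        la = -np.log10(np.maximum(assoc_a.loc[shared, "q"].to_numpy(float), 1e-300))
        lb = -np.log10(np.maximum(assoc_b.loc[shared, "q"].to_numpy(float), 1e-300))
    rho, rho_p = sps.spearmanr(la, lb)
    pearson_r = None
    n_top = None
    if importance_a is not None and importance_b is not None:
        common = importance_a.index.intersection(importance_b.index)
        if not common.empty:
            pearson_r = float(
                np.corrcoef(
                    importance_a.loc[common, "rank"], importance_b.loc[common, "rank"]
                )[0, 1]
            )
        top_a = set(importance_a.nsmallest(top_k, "rank").index)
        top_b = set(importance_b.nsmallest(top_k, "rank").index)
        n_top = len(top_a & top_b)
    return DefinitionComparison(
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        pearson_r=pearson_r,
        n_shared=len(shared),
        n_shared_top_k=n_top,
        top_k=top_k if n_top is not None else None,
    )
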