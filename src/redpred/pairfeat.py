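"""Pair-level feature engineering from gene-level attribute tables.

Gene-level columns are declared binary, categorical or continuous and carry a
feature-category tag (functional annotation, evolutionary property, protein
property, expression, epigenetic, network).  Pair-level features are built by
type-specific aggregation over the two genes of a pair:

* binary      -> count of genes carrying the annotation (0, 1 or 2)
* categorical -> overlap size, union size and percent overlap of token sets
* continuous  -> absolute difference, average, maximum, minimum and total

Aggregated columns are then expanded with per-column transformations (square,
log10, reciprocal and quartile binning) under one of two schemes: NT keeps only
untransformed aggregations, MT additionally emits every transformation.  (The
third scheme, BT, keeps each base feature's single best transformation and is
applied downstream during feature selection, where "best" is defined by model
importance.)  Quartile-bin edges, log/reciprocal zero offsets and imputation
medians are fitted on the training pairs and frozen, so feature values for new
pairs are computed on the training distribution without leakage.

All aggregations are symmetric in the two genes, so pair order never matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

DATA_TYPES = ("binary", "categorical", "continuous")
CATEGORIES = (
    "functional_annotation",
    "evolutionary",
    "protein",
    "expression",
    "epigenetic",
    "network",
)

#: aggregations per data type
BINARY_AGGS = ("count",)
CATEGORICAL_AGGS = ("n_overlap", "n_union", "pct_overlap")
CONTINUOUS_AGGS = ("diff", "avg", "max", "min", "total")

#: transform variants (identity first).  Binary counts skip quartile binning;
#: categorical summaries and continuous aggregations use all five.
BINARY_TRANSFORMS = ("identity", "square", "log10", "reciprocal")
FULL_TRANSFORMS = ("identity", "square", "log10", "reciprocal", "quartile_bin")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Declaration of one gene-level feature column."""

    name: str
    data_type: str
    category: str
    notes: str = ""

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"{self.name}: unknown data_type {self.data_type!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")


class GeneFeatureTable:
    """Gene-level attribute table plus per-column type declarations.

    Continuous/binary cells are floats; categorical cells hold frozensets of
    tokens (semicolon-separated in the TSV serialization).
    """

    def __init__(self, data: pd.DataFrame, schema: Sequence[FeatureDescriptor]):
        self.schema = {d.name: d for d in schema}
        unknown = [c for c in data.columns if c not in self.schema]
        if unknown:
            raise ValueError(f"columns without schema entry: {unknown}")
        self.data = data
        for d in self.schema.values():
            if d.name not in data.columns:
                raise ValueError(f"schema feature {d.name} missing from table")
            if d.data_type == "binary":
                col = data[d.name].dropna()
                bad = col[~col.isin([0, 1, 0.0, 1.0])]
                if not bad.empty:
                    raise TypeError(
                        f"binary column {d.name} has non-binary values "
                        f"(e.g. {bad.iloc[0]!r} for gene {bad.index[0]!r})"
                    )

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def descriptors(self, data_type: str | None = None) -> list[FeatureDescriptor]:
        descs = list(self.schema.values())
        if data_type is not None:
            descs = [d for d in descs if d.data_type == data_type]
        return descs

    def to_files(self, genes_path: str | Path, schema_path: str | Path) -> None:
        out = self.data.copy()
        for d in self.schema.values():
            if d.data_type == "categorical":
                out[d.name] = out[d.name].map(
                    lambda s: ";".join(sorted(s)) if isinstance(s, frozenset) else ""
                )
        out.to_csv(genes_path, sep="\t", index_label="gene")
        pd.DataFrame(
            [
                {"feature": d.name, "data_type": d.data_type, "category": d.category,
                 "notes": d.notes}
                for d in self.schema.values()
            ]
        ).to_csv(schema_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, genes_path: str | Path, schema_path: str | Path) -> "GeneFeatureTable":
        schema_df = pd.read_csv(schema_path, sep="\t").fillna({"notes": ""})
        schema = [
            FeatureDescriptor(r.feature, r.data_type, r.category, str(r.notes))
            for r in schema_df.itertuples()
        ]
        data = pd.read_csv(genes_path, sep="\t", index_col="gene")
        for d in schema:
            if d.data_type == "categorical":
                data[d.name] = data[d.name].map(
                    lambda s: frozenset(str(s).split(";"))
                    if isinstance(s, str) and s and s != "nan"
                    else frozenset()
                )
        return cls(data, schema)


# ---------------------------------------------------------------------------
# elementary pair aggregations


def binary_pair_feature(a: float, b: float) -> float:
    """Number of genes in the pair (0, 1 or 2) carrying a binary annotation."""
    for v in (a, b):
        if v not in (0, 1, 0.0, 1.0):
            raise TypeError(f"binary pair feature requires 0/1 inputs, got {v!r}")
    return float(a) + float(b)


def categorical_overlap(set_a: frozenset, set_b: frozenset) -> tuple[int, int, float]:
    """(overlap size, union size, percent overlap) of two annotation token sets."""
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    n_overlap = len(set_a & set_b)
    n_union = len(set_a | set_b)
    pct = 100.0 * n_overlap / n_union if n_union else 0.0
    return n_overlap, n_union, pct


def continuous_pair_features(x: float, y: float) -> tuple[float, float, float, float, float]:
    """(|x-y|, mean, max, min, sum) of a continuous gene-level value over a pair."""
    if pd.isna(x) or pd.isna(y):
        return (np.nan,) * 5
    return abs(x - y), (x + y) / 2.0, max(x, y), min(x, y), x + y


# ---------------------------------------------------------------------------
# column transforms


@dataclass
class TransformPolicy:
    """Deterministic per-column transform rules.

    Zero handling (the offsets are fitted per column and recorded):
    * log10 on a column containing 0 uses log10(x + delta) with delta = the
      smallest positive value in the fitting data; strictly positive columns
      use plain log10.
    * reciprocal replaces 0 by the smallest positive value before inversion.
    Columns containing negative values skip log10/reciprocal with a logged
    warning.  Quartile-bin ties take the lower bin.
    """

    transforms: tuple[str, ...] = FULL_TRANSFORMS


@dataclass
class ColumnState:
    """Fitted constants for one aggregated column (frozen after training)."""

    impute_value: float = np.nan
    delta_log: float | None = None      # None => plain log10; nan => skipped
    delta_recip: float | None = None
    bin_edges: np.ndarray | None = None
    skip: set = field(default_factory=set)  # transforms skipped (negatives)


def _fit_column_state(values: np.ndarray) -> ColumnState:
    state = ColumnState()
    finite = values[np.isfinite(values)]
    state.impute_value = float(np.median(finite)) if finite.size else 0.0
    filled = np.where(np.isfinite(values), values, state.impute_value)
    positive = filled[filled > 0]
    smallest_pos = float(positive.min()) if positive.size else 1.0
    if (filled < 0).any():
        state.skip |= {"log10", "reciprocal"}
    else:
        state.delta_log = 0.0 if (filled > 0).all() else smallest_pos
        state.delta_recip = smallest_pos
    if np.unique(filled).size < 4:
        logger.info("column has <4 distinct values; quartile bins under-populated")
    state.bin_edges = np.quantile(filled, [0.25, 0.5, 0.75])
    return state


def transform_column(
    values: np.ndarray, kind: str, state: ColumnState
) -> np.ndarray | None:
    """Apply one fitted transform; returns None when the transform is skipped."""
    values = np.asarray(values, dtype=float)
    if kind == "identity":
        return values
    if kind in state.skip:
        logger.warning("skipping %s on column with negative values", kind)
        return None
    if kind == "square":
        return values**2
    if kind == "log10":
        return np.log10(values + (state.delta_log or 0.0))
    if kind == "reciprocal":
        repl = np.where(values == 0, state.delta_recip, values)
        return 1.0 / repl
    if kind == "quartile_bin":
        return _bin_with_edges(values, state.bin_edges)
    raise ValueError(f"unknown transform {kind!r}")


def _bin_with_edges(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    out = np.searchsorted(edges, values, side="left") + 1.0
    out[~np.isfinite(values)] = np.nan
    return out


def quartile_bin(values: Sequence[float], edges: np.ndarray | None = None) -> np.ndarray:
    """Assign values to quartile bins 1..4 (ties take the lower bin).

    Edges default to the 25/50/75% empirical quantiles of the non-missing
    values; pass frozen training edges to bin new data without leakage.
    """
    values = np.asarray(values, dtype=float)
    if edges is None:
        finite = values[np.isfinite(values)]
        if finite.size < 4:
            raise ValueError("quartile binning needs >=4 non-missing values")
        if np.unique(finite).size < 4:
            logger.info("fewer than 4 distinct values; some bins unpopulated")
        edges = np.quantile(finite, [0.25, 0.5, 0.75])
    return _bin_with_edges(values, np.asarray(edges, dtype=float))


# ---------------------------------------------------------------------------
# the pair feature matrix


@dataclass
class PairFeatureMatrix:
    """Engineered pair-level features plus per-column provenance metadata.

    ``metadata`` is indexed by engineered column name with columns
    base / aggregation / transform / category / data_type, so every column
    resolves to exactly one base feature (or principal component).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate engineered column names: {list(dups)}")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"columns without metadata: {sorted(missing)}")

    def columns_for_base(self, base: str) -> list[str]:
        return list(self.metadata.index[self.metadata["base"] == base])

    def untransformed(self) -> "PairFeatureMatrix":
        keep = self.metadata.index[self.metadata["transform"] == "identity"]
        return PairFeatureMatrix(self.values[list(keep)], self.metadata.loc[keep])

    def to_files(self, values_path: str | Path, metadata_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="pair_id")
        self.metadata.to_csv(metadata_path, sep="\t", index_label="column")

    @classmethod
    def from_files(cls, values_path: str | Path, metadata_path: str | Path) -> "PairFeatureMatrix":
        return cls(
            pd.read_csv(values_path, sep="\t", index_col="pair_id"),
            pd.read_csv(metadata_path, sep="\t", index_col="column"),
        )


def _colname(base: str, agg: str, transform: str) -> str:
    name = f"{base}__{agg}"
    return name if transform == "identity" else f"{name}__{transform}"


class PairFeaturizer:
    """Builds pair feature matrices; fitted constants freeze on the first call.

    ``fit_transform`` learns imputation medians, log/reciprocal offsets and
    quartile-bin edges from the supplied (training) pairs; ``transform`` then
    applies the frozen state to new pairs.
    """

    def __init__(
        self,
        gene_table: GeneFeatureTable,
        scheme: str = "MT",
        policy: TransformPolicy | None = None,
    ):
        if scheme not in ("NT", "MT"):
            raise ValueError("scheme must be NT or MT (BT is applied at selection time)")
        self.gene_table = gene_table
        self.scheme = scheme
        self.policy = policy or TransformPolicy()
        self.states: dict[str, ColumnState] = {}
        self.fitted = False

    # -- aggregation ---------------------------------------------------------

    def _aggregate(self, pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        gt = self.gene_table
        all_genes = set(gt.genes)
        missing = sorted(
            (set(pairs["gene_a"]) | set(pairs["gene_b"])) - all_genes
        )
        if missing:
            raise KeyError(f"genes absent from the gene table: {missing}")
        idx_a = gt.data.loc[pairs["gene_a"]].reset_index(drop=True)
        idx_b = gt.data.loc[pairs["gene_b"]].reset_index(drop=True)
        cols: dict[str, np.ndarray] = {}
        meta_rows: list[dict] = []

        def add(base: str, agg: str, values: np.ndarray, category: str, dtype: str) -> None:
            name = f"{base}__{agg}"
            cols[name] = values
            meta_rows.append(
                {"column": name, "base": base, "aggregation": agg,
                 "transform": "identity", "category": category, "data_type": dtype}
            )

        for d in gt.schema.values():
            a = idx_a[d.name]
            b = idx_b[d.name]
            if d.data_type == "binary":
                add(d.name, "count", (a.to_numpy(float) + b.to_numpy(float)),
                    d.category, "binary")
            elif d.data_type == "categorical":
                trip = [categorical_overlap(x, y) for x, y in zip(a, b)]
                arr = np.array(trip, dtype=float).reshape(len(pairs), 3)
                for j, agg in enumerate(CATEGORICAL_AGGS):
                    add(d.name, agg, arr[:, j], d.category, "categorical")
            else:
                x = a.to_numpy(float)
                y = b.to_numpy(float)
                both = np.isfinite(x) & np.isfinite(y)
                outs = {
                    "diff": np.abs(x - y),
                    "avg": (x + y) / 2.0,
                    "max": np.maximum(x, y),
                    "min": np.minimum(x, y),
                    "total": x + y,
                }
                for agg, vals in outs.items():
                    vals = np.where(both, vals, np.nan)
                    add(d.name, agg, vals, d.category, "continuous")

        values = pd.DataFrame(cols, index=pd.Index(pairs["pair_id"], name="pair_id"))
        meta = pd.DataFrame(meta_rows).set_index("column")
        return values, meta

    # -- transforms ----------------------------------------------------------

    def _expand(
        self, agg_values: pd.DataFrame, agg_meta: pd.DataFrame, fit: bool
    ) -> PairFeatureMatrix:
        cols: dict[str, np.ndarray] = {}
        meta_rows: list[dict] = []
        for name in agg_values.columns:
            row = agg_meta.loc[name]
            raw = agg_values[name].to_numpy(float)
            if fit:
                self.states[name] = _fit_column_state(raw)
            state = self.states[name]
            filled = np.where(np.isfinite(raw), raw, state.impute_value)
            if row["data_type"] == "binary":
                variants = BINARY_TRANSFORMS
            else:
                variants = self.policy.transforms
            if self.scheme == "NT":
                variants = ("identity",)
            for kind in variants:
                out = transform_column(filled, kind, state)
                if out is None:
                    continue
                cname = _colname(row["base"], row["aggregation"], kind)
                cols[cname] = out
                meta_rows.append(
                    {"column": cname, "base": row["base"],
                     "aggregation": row["aggregation"], "transform": kind,
                     "category": row["category"], "data_type": row["data_type"]}
                )
        values = pd.DataFrame(cols, index=agg_values.index)
        meta = pd.DataFrame(meta_rows).set_index("column")
        return PairFeatureMatrix(values, meta)

    def fit_transform(self, pairs: pd.DataFrame) -> PairFeatureMatrix:
        agg_values, agg_meta = self._aggregate(pairs)
        matrix = self._expand(agg_values, agg_meta, fit=True)
        self.fitted = True
        return matrix

    def transform(self, pairs: pd.DataFrame) -> PairFeatureMatrix:
        if not self.fitted:
            raise RuntimeError("featurizer not fitted; call fit_transform first")
        agg_values, agg_meta = self._aggregate(pairs)
        return self._expand(agg_values, agg_meta, fit=False)


def build_pair_matrix(
    gene_table: GeneFeatureTable,
    pairs: pd.DataFrame,
    policy: TransformPolicy | None = None,
    scheme: str = "MT",
) -> PairFeatureMatrix:
    """One-shot pair feature matrix (fits transform constants on these pairs)."""
    return PairFeaturizer(gene_table, scheme=scheme, policy=policy).fit_transform(pairs)


def pca_features(
    matrix: PairFeatureMatrix, n_components: int = 5, random_state: int = 0
) -> PairFeatureMatrix:
    """Append the top principal-component scores of the full feature matrix.

    The matrix must already be imputed (the featurizer guarantees this).  PC
    score columns are orthogonal and ordered by non-increasing explained
    variance.
    """
    X = matrix.values.to_numpy(float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    pca = PCA(n_components=n_components, random_state=random_state)
    scores = pca.fit_transform(X)
    values = matrix.values.copy()
    meta = matrix.metadata.copy()
    new_meta = []
    for k in range(n_components):
        name = f"PC_{k + 1}"
        values[name] = scores[:, k]
        new_meta.append(
            {"column": name, "base": "PCA", "aggregation": name,
             "transform": "identity", "category": "derived", "data_type": "continuous"}
        )
    meta = pd.concat([meta, pd.DataFrame(new_meta).set_index("column")])
    return PairFeatureMatrix(values, meta)
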