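"""Statsmodels-style modelling interface.

:class:`RedundancyModel` is built from a mutant-trio table and a gene-level
feature table; ``fit`` runs the full protocol (labeling, holdout split, pair
feature engineering frozen on the training split, optional grid search,
feature selection, balanced-ensemble training) and returns a
:class:`RedundancyResults` carrying the ensemble, cross-validation and holdout
performance, feature importances and diagnostics.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import interpret, mlcore, phenotypes, stats
from .mlcore import EvaluationSummary, ModelEnsemble, SelectionConfig
from .pairfeat import GeneFeatureTable, PairFeaturizer, PairFeatureMatrix, TransformPolicy
from .phenotypes import DefinitionRuleTable, LabeledDataset, MutantTrio


class RedundancyModel:
    """Predicts whether a paralogous gene pair is genetically redundant.

    Parameters
    ----------
    trios : list of MutantTrio
        The benchmark mutant trios.
    gene_table : GeneFeatureTable
        Gene-level attributes with type/category declarations.
    definition : str
        Redundancy definition providing the positive class (e.g. "RD9"
        inclusive, "RD4" extreme).  Negatives are always the NR pairs.
    algorithm : str
        "svm" (linear kernel), "random_forest" or "gradient_boosting".
    n_features, selection_method, scheme
        Feature-selection configuration (top-k, random_forest/elastic_net,
        NT/MT/BT).
    n_replicates, cv_folds, holdout_fraction
        Balanced-ensemble protocol sizes.
    grid : dict or None
        Hyperparameter grid; None uses the built-in default for the
        algorithm, a single-point grid skips the search.
    """

    def __init__(
        self,
        trios: Sequence[MutantTrio],
        gene_table: GeneFeatureTable,
        definition: str = "RD9",
        algorithm: str = "svm",
        n_features: int = 200,
        selection_method: str = "random_forest",
        scheme: str = "BT",
        n_replicates: int = 100,
        cv_folds: int = 10,
        holdout_fraction: float = 0.1,
        grid: dict | None = None,
        rule_table: DefinitionRuleTable | None = None,
        transform_policy: TransformPolicy | None = None,
    ):
        if definition not in phenotypes.DEFINITIONS or definition == "NR":
            raise ValueError(f"definition must be one of RD1..RD9, got {definition!r}")
        self.trios = list(trios)
        self.gene_table = gene_table
        self.definition = definition
        self.algorithm = algorithm
        self.n_features = n_features
        self.selection_method = selection_method
        self.scheme = scheme
        self.n_replicates = n_replicates
        self.cv_folds = cv_folds
        self.holdout_fraction = holdout_fraction
        self.grid = grid
        self.rule_table = rule_table or DefinitionRuleTable.default()
        self.transform_policy = transform_policy
        self.dataset: LabeledDataset = phenotypes.label_dataset(
            self.trios, self.rule_table
        )

    @classmethod
    def from_files(
        cls,
        trios_path: str | Path,
        genes_path: str | Path,
        schema_path: str | Path,
        **kwargs,
    ) -> "RedundancyModel":
        return cls(
            phenotypes.load_trios(trios_path),
            GeneFeatureTable.from_files(genes_path, schema_path),
            **kwargs,
        )

    # ------------------------------------------------------------------

    def _instance_labels(self) -> pd.Series:
        """Boolean label per usable pair: definition-positive vs NR.

        Pairs that are redundant under RD9 but not under the chosen definition
        are excluded (they are neither positives nor negatives here).
        """
        df = self.dataset.labels
        usable = df[self.definition] | df["NR"]
        return df.loc[usable, self.definition].astype(bool)

    def fit(self, seed: int = 0, grid_replicates: int = 10) -> "RedundancyResults":
        rng = np.random.default_rng(seed)
        seeds = {
            name: int(rng.integers(0, 2**31 - 1))
            for name in ("holdout", "replicates", "grid", "selection", "ensemble")
        }
        labels = self._instance_labels()
        pairs_df = self.dataset.labels.loc[labels.index, ["gene_a", "gene_b"]]
        pairs_df = pairs_df.reset_index()

        train_ids, test_ids = mlcore.split_holdout(
            labels, self.holdout_fraction, seeds["holdout"]
        )
        scheme_for_matrix = "NT" if self.scheme == "NT" else "MT"
        featurizer = PairFeaturizer(
            self.gene_table, scheme=scheme_for_matrix, policy=self.transform_policy
        )
        train_matrix = featurizer.fit_transform(
            pairs_df[pairs_df["pair_id"].isin(train_ids)]
        )
        X_train = train_matrix.values
        y_train = labels.loc[X_train.index]

        balanced = mlcore.balanced_replicates(
            y_train, self.n_replicates, seeds["replicates"]
        )
        grid = self.grid if self.grid is not None else mlcore.DEFAULT_GRIDS[self.algorithm]
        n_points = int(np.prod([len(v) for v in grid.values()]))
        if n_points > 1:
            hyperparams = mlcore.grid_search_cv(
                X_train,
                y_train,
                self.algorithm,
                balanced,
                grid=grid,
                folds=self.cv_folds,
                n_balanced=grid_replicates,
                seed=seeds["grid"],
            )
        else:
            hyperparams = {k: v[0] for k, v in grid.items()}

        config = SelectionConfig(
            method=self.selection_method,
            k=min(self.n_features, X_train.shape[1]),
            scheme=self.scheme,
        )
        # k is clamped to the candidate pool (the BT collapse can leave fewer
        # columns than requested on small feature schemas)
        selected = mlcore.select_features(
            X_train, y_train, train_matrix.metadata, config, balanced,
            seed=seeds["selection"], clamp=True,
        )
        ensemble = mlcore.train_ensemble(
            X_train,
            y_train,
            self.algorithm,
            hyperparams,
            selected,
            n_replicates=self.n_replicates,
            folds=self.cv_folds,
            seed=seeds["ensemble"],
            balanced_sets=balanced,
        )
        cv_summary = mlcore.evaluate_cv(ensemble)

        holdout_summary = None
        test_matrix = None
        y_test = None
        if len(test_ids) > 0:
            test_matrix = featurizer.transform(
                pairs_df[pairs_df["pair_id"].isin(test_ids)]
            )
            y_test = labels.loc[test_matrix.values.index]
            if y_test.nunique() == 2:
                holdout_summary = mlcore.evaluate(
                    ensemble, test_matrix.values, y_test
                )
        return RedundancyResults(
            model=self,
            featurizer=featurizer,
            train_matrix=train_matrix,
            test_matrix=test_matrix,
            y_train=y_train,
            y_test=y_test,
            ensemble=ensemble,
            hyperparams=hyperparams,
            cv_summary=cv_summary,
            holdout_summary=holdout_summary,
            seed=seed,
            sub_seeds=seeds,
        )


@dataclass
class RedundancyResults:
    """Fitted redundancy model: ensemble, performance, importances."""

    model: RedundancyModel
    featurizer: PairFeaturizer
    train_matrix: PairFeatureMatrix
    test_matrix: PairFeatureMatrix | None
    y_train: pd.Series
    y_test: pd.Series | None
    ensemble: ModelEnsemble
    hyperparams: dict
    cv_summary: EvaluationSummary
    holdout_summary: EvaluationSummary | None
    seed: int
    sub_seeds: dict

    # -- inference ------------------------------------------------------

    @property
    def importances(self) -> pd.DataFrame:
        return mlcore.feature_importance(self.ensemble)

    def predict(self, pairs: pd.DataFrame | None = None) -> pd.DataFrame:
        """Redundancy scores and calls for new pairs (pair_id/gene_a/gene_b
        DataFrame) or, by default, the training pairs."""
        if pairs is None:
            X = self.train_matrix.values
        else:
            X = self.featurizer.transform(pairs).values
        return mlcore.predict_scores(self.ensemble, X)

    def associations(self) -> pd.DataFrame:
        """Univariate feature-class association tests on the training matrix."""
        return stats.associate_features(self.train_matrix, self.y_train)

    def misprediction_report(self, **kwargs) -> interpret.MispredictionReport:
        """Separation-score and PCA diagnostics of training-pair mispredictions,
        restricted to the model's selected features."""
        preds = mlcore.predict_scores(self.ensemble, self.train_matrix.values)
        selected = [
            f for f in self.ensemble.selected_features
            if f in self.train_matrix.values.columns
        ]
        sub = self.train_matrix.values[selected]
        return interpret.misprediction_report(
            sub, self.y_train, preds["call"], self.importances, **kwargs
        )

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Redundancy prediction ensemble",
            "=" * 46,
            f"definition            {self.model.definition}",
            f"algorithm             {self.ensemble.algorithm}",
            f"hyperparameters       {self.hyperparams}",
            f"scheme / selection    {self.model.scheme} / {self.model.selection_method}",
            f"selected features     {len(self.ensemble.selected_features)}",
            f"ensemble members      {self.ensemble.n_replicates}",
            f"decision threshold    {self.ensemble.threshold:.3f}",
            f"training pairs        {len(self.y_train)} "
            f"({int(self.y_train.sum())} redundant / "
            f"{int((~self.y_train).sum())} nonredundant)",
            "-" * 46,
            f"CV AUC-ROC            {self.cv_summary.auc_roc:.3f}",
            f"CV AU-PRC             {self.cv_summary.au_prc:.3f}",
            f"CV F1 @ threshold     {self.cv_summary.f1:.3f}",
        ]
        if self.holdout_summary is not None:
            lines += [
                f"holdout AUC-ROC       {self.holdout_summary.auc_roc:.3f}",
                f"holdout AU-PRC        {self.holdout_summary.au_prc:.3f}",
            ]
        top = self.importances.head(5)
        lines.append("-" * 46)
        lines.append("top features (mean |weight|):")
        for feat, row in top.iterrows():
            lines.append(f"  {row['rank']:>3.0f}  {feat}  {row['importance']:.4f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None, label: str | None = None):
        """Averaged ROC curve with +/- 1 SD band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.cv_summary
        ax.plot(s.fpr_grid, s.tpr_mean, label=label or f"AUC-ROC {s.auc_roc:.2f}")
        ax.fill_between(
            s.fpr_grid, s.tpr_mean - s.tpr_sd, s.tpr_mean + s.tpr_sd, alpha=0.2
        )
        ax.plot([0, 1], [0, 1], "k:", lw=1)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax

    def plot_pr(self, ax=None, label: str | None = None):
        """Averaged precision-recall curve with +/- 1 SD band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.cv_summary
        ax.plot(s.recall_grid, s.precision_mean, label=label or f"AU-PRC {s.au_prc:.2f}")
        ax.fill_between(
            s.recall_grid,
            s.precision_mean - s.precision_sd,
            s.precision_mean + s.precision_sd,
            alpha=0.2,
        )
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
        ax.legend()
        return ax

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Serialized ensemble + JSON manifest (features, thresholds, seeds)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import sklearn

        manifest = {
            "definition": self.model.definition,
            "algorithm": self.ensemble.algorithm,
            "hyperparameters": self.hyperparams,
            "selected_features": self.ensemble.selected_features,
            "thresholds": [m.threshold for m in self.ensemble.members],
            "ensemble_threshold": self.ensemble.threshold,
            "seed": self.seed,
            "sub_seeds": self.sub_seeds,
            "versions": {
                "sklearn": sklearn.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        with open(directory / "results.pkl", "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(directory: str | Path) -> "RedundancyResults":
        with open(Path(directory) / "results.pkl", "rb") as fh:
            return pickle.load(fh)
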