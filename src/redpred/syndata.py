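"""Synthetic benchmark generator with planted, tunable redundancy signal.

Emulates the statistical shape of a mutant-trio benchmark: ~300 gene pairs at
a 190:110 redundant:nonredundant balance, a mixed-type gene attribute table
spanning the six feature categories, and phenotype classes emitted from
trio-type tables conditional on each pair's latent redundancy state.  Planted
effects shift a handful of features between the latent classes — by default a
recent-whole-genome-duplication-like binary flag and a reciprocal-best-match
flag are enriched among redundant pairs (log-odds +2), five continuous
features are shifted by 1.5 SD (substitution rates and stress-response
breadths lowered for redundant pairs, expression similarity raised), and
redundant pairs co-occur in the same coexpression cluster more often.  All
other columns are pure noise.  With zero emission noise the phenotype labels
recover the latent states exactly, so the generator doubles as an oracle for
end-to-end pipeline tests.

Latent states are stratified-exact by default (exactly round(pi * n) redundant
pairs); set ``balance="binomial"`` for independent Bernoulli draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pairfeat import FeatureDescriptor, GeneFeatureTable
from .phenotypes import MutantTrio

# trio-type emission tables: (sm_a, sm_b, dm) -> probability, conditional on
# the latent redundancy state.  Redundant types keep the double mutant strictly
# more severe than both single mutants (the lethal-DM cell is weighted so the
# extreme-redundancy subset is well populated at n = 300); nonredundant types
# never do.
REDUNDANT_EMISSION: dict[tuple[str, str, str], float] = {
    ("0", "0", "2"): 0.30,
    ("0", "0", "1C"): 0.20,
    ("0", "0", "1B"): 0.06,
    ("0", "0", "1A"): 0.09,
    ("1A", "0", "1B"): 0.07,
    ("1A", "0", "1C"): 0.08,
    ("1B", "1A", "1C"): 0.05,
    ("1A", "0", "2"): 0.08,
    ("1B", "0", "2"): 0.04,
    ("1C", "1B", "2"): 0.03,
}
NONREDUNDANT_EMISSION: dict[tuple[str, str, str], float] = {
    ("0", "0", "0"): 0.25,
    ("1A", "0", "0"): 0.10,
    ("1C", "0", "1A"): 0.15,
    ("1C", "1C", "1C"): 0.10,
    ("1B", "1B", "0"): 0.10,
    ("2", "0", "1B"): 0.10,
    ("1B", "0", "1B"): 0.10,
    ("2", "2", "2"): 0.10,
}


@dataclass(frozen=True)
class PlantedEffect:
    """One feature shifted between the latent redundancy classes.

    ``effect`` is a log-odds shift for binary features, a standardized mean
    shift (in SD of the underlying normal) for continuous features, and a
    same-cluster co-membership probability for categorical cluster features.
    """

    feature: str
    kind: str       # binary | continuous | categorical
    effect: float


def default_planted_effects() -> list[PlantedEffect]:
    return [
        PlantedEffect("alpha_wgd", "binary", 2.0),
        PlantedEffect("reciprocal_best_match", "binary", 2.0),
        PlantedEffect("ks", "continuous", -1.5),
        PlantedEffect("ka", "continuous", -1.5),
        PlantedEffect("biotic_down_breadth", "continuous", -1.5),
        PlantedEffect("hormone_de_breadth", "continuous", -1.5),
        PlantedEffect("stress_expr_similarity", "continuous", 1.5),
        PlantedEffect("stress_coexpr_cluster_k25", "categorical", 0.6),
    ]


# gene-level feature schema: (name, data_type, category, family, params)
# family: "bernoulli" p | "lognormal" (mu, sigma) | "uniform" (lo, hi)
# | "tokens" (vocab_size, max_per_gene) | "cluster" n_clusters
_SCHEMA: list[tuple[str, str, str, str, tuple]] = [
    ("transcription_factor", "binary", "functional_annotation", "bernoulli", (0.2,)),
    ("other_biological_process", "binary", "functional_annotation", "bernoulli", (0.4,)),
    ("dnase_peak", "binary", "epigenetic", "bernoulli", (0.5,)),
    ("gene_body_methylation", "binary", "epigenetic", "bernoulli", (0.3,)),
    ("alpha_wgd", "binary", "evolutionary", "bernoulli", (0.25,)),
    ("reciprocal_best_match", "binary", "evolutionary", "bernoulli", (0.3,)),
    ("go_terms", "categorical", "functional_annotation", "tokens", (12, 4)),
    ("stress_coexpr_cluster_k25", "categorical", "network", "cluster", (25,)),
    ("ks", "continuous", "evolutionary", "lognormal", (0.0, 0.6)),
    ("ka", "continuous", "evolutionary", "lognormal", (-1.0, 0.6)),
    ("lethality_score", "continuous", "evolutionary", "uniform", (0.0, 1.0)),
    ("expression_level", "continuous", "expression", "lognormal", (2.0, 1.0)),
    ("expression_breadth", "continuous", "expression", "lognormal", (2.5, 0.5)),
    ("biotic_down_breadth", "continuous", "expression", "lognormal", (1.5, 0.7)),
    ("hormone_de_breadth", "continuous", "expression", "lognormal", (1.0, 0.7)),
    ("stress_expr_similarity", "continuous", "expression", "lognormal", (0.0, 0.5)),
    ("cpg_methylation_pct", "continuous", "epigenetic", "uniform", (0.0, 100.0)),
    ("chh_methylation_pct", "continuous", "epigenetic", "uniform", (0.0, 100.0)),
    ("isoelectric_point", "continuous", "protein", "uniform", (4.0, 11.0)),
    ("aa_length", "continuous", "protein", "lognormal", (6.0, 0.5)),
    ("aranet_degree", "continuous", "network", "lognormal", (2.0, 0.8)),
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark."""

    n_pairs: int = 300
    prevalence: float = 190 / 300
    balance: str = "exact"          # "exact" | "binomial"
    n_genes: int = 700
    allow_shared_genes: bool = True
    gene_share_prob: float = 0.03   # chance a pair reuses an already-used gene
    planted: list[PlantedEffect] = field(default_factory=default_planted_effects)
    effect_scale: float = 1.0       # multiplies every planted effect
    emission_noise: float = 0.0     # P(trio drawn from the wrong class's table)
    redundant_emission: dict = field(default_factory=lambda: dict(REDUNDANT_EMISSION))
    nonredundant_emission: dict = field(
        default_factory=lambda: dict(NONREDUNDANT_EMISSION)
    )

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.balance not in ("exact", "binomial"):
            raise ValueError("balance must be 'exact' or 'binomial'")
        for table in (self.redundant_emission, self.nonredundant_emission):
            total = sum(table.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"emission table sums to {total}, not 1")

    @property
    def planted_features(self) -> list[str]:
        return [e.feature for e in self.planted]


@dataclass
class SyntheticTruth:
    """Ground truth withheld from the pipeline; for tests and scoring only."""

    latent: pd.Series               # pair_id -> bool (redundant)
    planted_features: list[str]

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(
            {"pair_id": self.latent.index, "redundant": self.latent.astype(int)}
        ).to_csv(path, sep="\t", index=False)


def _schema_descriptors() -> list[FeatureDescriptor]:
    return [FeatureDescriptor(n, t, c) for n, t, c, _, _ in _SCHEMA]


def _base_value(rng: np.random.Generator, family: str, params: tuple):
    if family == "bernoulli":
        return float(rng.random() < params[0])
    if family == "lognormal":
        mu, sigma = params
        return float(np.exp(rng.normal(mu, sigma)))
    if family == "uniform":
        lo, hi = params
        return float(rng.uniform(lo, hi))
    if family == "tokens":
        vocab, max_per = params
        k = int(rng.integers(1, max_per + 1))
        return frozenset(f"tok{i}" for i in rng.choice(vocab, size=k, replace=False))
    if family == "cluster":
        return frozenset({f"c{int(rng.integers(params[0]))}"})
    raise ValueError(family)


def _planted_value(
    rng: np.random.Generator,
    family: str,
    params: tuple,
    effect: float,
    redundant: bool,
):
    """Value of a planted feature conditional on the latent state.

    Binary: log-odds shifted under redundancy.  Lognormal: the underlying
    normal is shifted by effect * sigma.  Uniform: shifted by effect * SD of
    the uniform and clipped to the range.
    """
    shift = effect if redundant else 0.0
    if family == "bernoulli":
        p0 = params[0]
        logit = np.log(p0 / (1 - p0)) + shift
        p = 1.0 / (1.0 + np.exp(-logit))
        return float(rng.random() < p)
    if family == "lognormal":
        mu, sigma = params
        return float(np.exp(rng.normal(mu + shift * sigma, sigma)))
    if family == "uniform":
        lo, hi = params
        sd = (hi - lo) / np.sqrt(12.0)
        return float(np.clip(rng.uniform(lo, hi) + shift * sd, lo, hi))
    raise ValueError(f"cannot plant effect on family {family!r}")


def generate_gene_table(
    config: SyntheticConfig, seed: int = 0, n_genes: int | None = None
) -> GeneFeatureTable:
    """Gene attribute table with base (no planted signal) distributions."""
    rng = np.random.default_rng(seed)
    n = n_genes if n_genes is not None else config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    data: dict[str, list] = {}
    for name, _, _, family, params in _SCHEMA:
        data[name] = [_base_value(rng, family, params) for _ in range(n)]
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return GeneFeatureTable(df, _schema_descriptors())


def generate_benchmark(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[list[MutantTrio], GeneFeatureTable, SyntheticTruth]:
    """Full synthetic benchmark: trios, gene table and withheld truth."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)

    # latent redundancy states
    n = config.n_pairs
    if config.balance == "exact":
        n_red = int(round(config.prevalence * n))
        latent = np.zeros(n, dtype=bool)
        latent[rng.choice(n, size=n_red, replace=False)] = True
    else:
        latent = rng.random(n) < config.prevalence

    planted_by_name = {e.feature: e for e in config.planted}
    schema_by_name = {name: (family, params) for name, _, _, family, params in _SCHEMA}

    # assign gene ids pair by pair (optionally reusing genes across pairs)
    used: list[str] = []
    gene_values: dict[str, dict] = {}
    pair_rows = []
    counter = 0

    def new_gene(redundant: bool, cluster_partner: str | None) -> str:
        nonlocal counter
        gid = f"g{counter:05d}"
        counter += 1
        values: dict = {}
        for name, _, _, family, params in _SCHEMA:
            eff = planted_by_name.get(name)
            if eff is not None and eff.kind in ("binary", "continuous"):
                values[name] = _planted_value(
                    rng, family, params, eff.effect * config.effect_scale, redundant
                )
            elif eff is not None and eff.kind == "categorical":
                # cluster co-membership handled at pair level below
                values[name] = _base_value(rng, family, params)
            else:
                values[name] = _base_value(rng, family, params)
        gene_values[gid] = values
        if cluster_partner is not None:
            for name, e in planted_by_name.items():
                if e.kind != "categorical":
                    continue
                p_co = min(1.0, e.effect * config.effect_scale)
                if redundant and rng.random() < p_co:
                    values[name] = gene_values[cluster_partner][name]
        return gid

    for i in range(n):
        r = bool(latent[i])
        reuse_a = (
            config.allow_shared_genes and used and rng.random() < config.gene_share_prob
        )
        gene_a = used[int(rng.integers(len(used)))] if reuse_a else new_gene(r, None)
        gene_b = new_gene(r, gene_a)
        used.extend([gene_a, gene_b])
        pair_rows.append((f"p{i:04d}", gene_a, gene_b, r))

    # phenotype emission
    trios = []
    for pair_id, gene_a, gene_b, r in pair_rows:
        emit_red = r if rng.random() >= config.emission_noise else not r
        table = config.redundant_emission if emit_red else config.nonredundant_emission
        keys = list(table)
        probs = np.array([table[k] for k in keys])
        sm_a, sm_b, dm = keys[rng.choice(len(keys), p=probs / probs.sum())]
        if rng.random() < 0.5:  # pairs are unordered
            sm_a, sm_b = sm_b, sm_a
        trios.append(MutantTrio(pair_id, gene_a, gene_b, sm_a, sm_b, dm))

    gene_df = pd.DataFrame.from_dict(gene_values, orient="index").rename_axis("gene")
    gene_table = GeneFeatureTable(gene_df, _schema_descriptors())
    truth = SyntheticTruth(
        latent=pd.Series(
            latent, index=pd.Index([p for p, *_ in pair_rows], name="pair_id")
        ),
        planted_features=list(planted_by_name),
    )
    return trios, gene_table, truth
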