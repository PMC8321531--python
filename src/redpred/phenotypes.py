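"""Phenotype severity classes and redundancy definitions for mutant trios.

A *mutant trio* is a paralogous gene pair together with the phenotype class of
each single loss-of-function mutant and of the double mutant.  Phenotype
severity is ordinal on five classes::

    0   no abnormal phenotype
    1A  conditional phenotype
    1B  cellular / biochemical phenotype
    1C  morphological phenotype
    2   lethal

A pair is *nonredundant* (NR) when at least one single mutant is as severe as,
or more severe than, the double mutant; otherwise the double mutant uncovers
hidden overlap in function and the pair is *redundant* under the inclusive
definition (RD9).  Finer-grained definitions RD1-RD8 key on which severity
cells the trio occupies: RD1-RD4 ("classic" redundancy, RD5 = their union)
require both single mutants to be class 0, with the double mutant 1A/1B/1C/2
respectively; RD6-RD8 ("subtle" redundancy) allow an abnormal single mutant as
long as both are strictly milder than the double mutant, keyed by double-mutant
class 1B/1C/2.  RD9 is the union of RD1-RD8.

The RD1-RD8 cell assignment is held in a :class:`DefinitionRuleTable` that can
be overridden from a YAML file; the invariants (RD5 = RD1..RD4, RD9 = RD1..RD8,
RD9/NR an exhaustive partition) are verified on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

PHENOTYPE_CODES: tuple[str, ...] = ("0", "1A", "1B", "1C", "2")
_CODE_TO_RANK = {code: rank for rank, code in enumerate(PHENOTYPE_CODES)}

#: Definitions in canonical order.  RD5 and RD9 are derived unions; NR is the
#: complement of RD9.
SUB_DEFINITIONS = ("RD1", "RD2", "RD3", "RD4", "RD6", "RD7", "RD8")
DEFINITIONS = ("RD1", "RD2", "RD3", "RD4", "RD5", "RD6", "RD7", "RD8", "RD9", "NR")


def severity_rank(code: str) -> int:
    """Integer severity rank of a phenotype class code (0 for "0" ... 4 for "2")."""
    try:
        return _CODE_TO_RANK[str(code)]
    except KeyError:
        raise ValueError(
            f"unknown phenotype class {code!r}; expected one of {PHENOTYPE_CODES}"
        ) from None


def rank_to_code(rank: int) -> str:
    return PHENOTYPE_CODES[rank]


@dataclass(frozen=True)
class MutantTrio:
    """A gene pair with two single-mutant classes and one double-mutant class."""

    pair_id: str
    gene_a: str
    gene_b: str
    sm_a: str
    sm_b: str
    dm: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"trio {self.pair_id}: gene_a == gene_b ({self.gene_a})")
        for attr in ("sm_a", "sm_b", "dm"):
            severity_rank(getattr(self, attr))

    @property
    def max_sm_rank(self) -> int:
        return max(severity_rank(self.sm_a), severity_rank(self.sm_b))

    @property
    def dm_rank(self) -> int:
        return severity_rank(self.dm)


# Redundancy region of the (max single-mutant rank, double-mutant rank) plane:
# the double mutant strictly more severe than both single mutants.
_REDUNDANT_CELLS = frozenset(
    (m, d) for m in range(5) for d in range(5) if d > m
)

_DEFAULT_RULES: dict[str, frozenset[tuple[int, int]]] = {
    "RD1": frozenset({(0, 1)}),
    "RD2": frozenset({(0, 2)}),
    "RD3": frozenset({(0, 3)}),
    "RD4": frozenset({(0, 4)}),
    "RD6": frozenset({(1, 2)}),
    "RD7": frozenset({(1, 3), (2, 3)}),
    "RD8": frozenset({(1, 4), (2, 4), (3, 4)}),
}


class DefinitionRuleTable:
    """Maps sub-definitions RD1-RD8 to cells of the (max SM rank, DM rank) plane.

    Trios are unordered pairs, so predicates are written over the maximum
    single-mutant rank only (the minimum never decides membership under the
    default table).  RD5 and RD9 are always the unions RD1-4 and RD1-8; NR is
    the complement of the redundancy region.
    """

    def __init__(
        self,
        rules: Mapping[str, Iterable[tuple[int, int]]] | None = None,
        provenance: str = "default",
    ) -> None:
        if rules is None:
            rules = _DEFAULT_RULES
            provenance = "default"
        self.rules: dict[str, frozenset[tuple[int, int]]] = {
            name: frozenset((int(m), int(d)) for m, d in cells)
            for name, cells in rules.items()
        }
        self.provenance = provenance
        self._validate()

    def _validate(self) -> None:
        missing = set(SUB_DEFINITIONS) - set(self.rules)
        if missing:
            raise ValueError(f"rule table missing definitions: {sorted(missing)}")
        union: set[tuple[int, int]] = set()
        for name, cells in self.rules.items():
            for cell in cells:
                if cell not in _REDUNDANT_CELLS:
                    raise ValueError(
                        f"{name}: cell {cell} lies outside the redundancy region "
                        "(double mutant must outrank both single mutants)"
                    )
                if cell in union:
                    raise ValueError(f"{name}: cell {cell} assigned to two definitions")
            union |= set(cells)
        if union != _REDUNDANT_CELLS:
            uncovered = sorted(_REDUNDANT_CELLS - union)
            raise ValueError(
                f"RD1-RD8 do not cover the redundancy region; uncovered cells: {uncovered}"
            )

    @classmethod
    def default(cls) -> "DefinitionRuleTable":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DefinitionRuleTable":
        """Load a user rule table.

        Format: one block per sub-definition listing allowed combinations of
        max single-mutant rank and double-mutant rank::

            RD1:
              - {max_sm: [0], dm: [1]}
        """
        raw = yaml.safe_load(Path(path).read_text())
        rules: dict[str, set[tuple[int, int]]] = {}
        for name, blocks in raw.items():
            cells: set[tuple[int, int]] = set()
            for block in blocks:
                for m in block["max_sm"]:
                    for d in block["dm"]:
                        cells.add((int(m), int(d)))
            rules[name] = cells
        return cls(rules, provenance="user-supplied")

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            name: [{"max_sm": [m], "dm": [d]} for m, d in sorted(cells)]
            for name, cells in sorted(self.rules.items())
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    def label(self, max_sm_rank: int, dm_rank: int) -> frozenset[str]:
        """Definitions applying to a trio with the given rank pair."""
        cell = (max_sm_rank, dm_rank)
        if cell not in _REDUNDANT_CELLS:
            return frozenset({"NR"})
        labels = {name for name, cells in self.rules.items() if cell in cells}
        if labels & {"RD1", "RD2", "RD3", "RD4"}:
            labels.add("RD5")
        labels.add("RD9")
        return frozenset(labels)


def label_trio(trio: MutantTrio, rules: DefinitionRuleTable | None = None) -> frozenset[str]:
    """Label one trio: the applicable RD1-RD8 flags plus RD5/RD9 or NR.

    Exactly one of RD9/NR is always present: NR iff the more severe single
    mutant is at least as severe as the double mutant.
    """
    if rules is None:
        rules = DefinitionRuleTable.default()
    return rules.label(trio.max_sm_rank, trio.dm_rank)


@dataclass
class LabeledDataset:
    """Trios with per-definition binary labels.

    ``labels`` is indexed by pair_id with one boolean column per definition in
    :data:`DEFINITIONS` plus gene_a/gene_b columns for downstream joins.
    """

    trios: list[MutantTrio]
    labels: pd.DataFrame
    rules: DefinitionRuleTable = field(default_factory=DefinitionRuleTable.default)

    def counts(self) -> pd.Series:
        return count_by_definition(self)


def label_dataset(
    trios: Iterable[MutantTrio], rules: DefinitionRuleTable | None = None
) -> LabeledDataset:
    if rules is None:
        rules = DefinitionRuleTable.default()
    trios = list(trios)
    rows = []
    for t in trios:
        labels = label_trio(t, rules)
        row = {"pair_id": t.pair_id, "gene_a": t.gene_a, "gene_b": t.gene_b}
        row.update({d: d in labels for d in DEFINITIONS})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("pair_id")
    ds = LabeledDataset(trios=trios, labels=df, rules=rules)
    # partition invariant
    assert (df["RD9"] ^ df["NR"]).all(), "RD9/NR must partition the trios"
    return ds


def count_by_definition(dataset: LabeledDataset) -> pd.Series:
    """Number of trios assigned to each definition (RD1..RD9 and NR)."""
    return dataset.labels[list(DEFINITIONS)].sum().astype(int)


def load_trios(path: str | Path) -> list[MutantTrio]:
    """Read a trios.tsv with columns pair_id, gene_a, gene_b, sm_a_class,
    sm_b_class, dm_class.  Duplicate pair_ids are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["pair_id", "gene_a", "gene_b", "sm_a_class", "sm_b_class", "dm_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trios file {path} missing columns: {missing}")
    dup = df["pair_id"][df["pair_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate pair_ids in {path}: {sorted(dup.unique())}")
    return [
        MutantTrio(
            pair_id=r.pair_id,
            gene_a=r.gene_a,
            gene_b=r.gene_b,
            sm_a=r.sm_a_class,
            sm_b=r.sm_b_class,
            dm=r.dm_class,
        )
        for r in df.itertuples()
    ]


def save_trios(trios: Iterable[MutantTrio], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "pair_id": t.pair_id,
                "gene_a": t.gene_a,
                "gene_b": t.gene_b,
                "sm_a_class": t.sm_a,
                "sm_b_class": t.sm_b,
                "dm_class": t.dm,
            }
            for t in trios
        ]
    ).to_csv(path, sep="\t", index=False)
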