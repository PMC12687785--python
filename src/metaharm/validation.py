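"""Value-level validation: dynamic enums, logical constraints, error triage.

A *dynamic enumeration node* is an ontology term whose descendant set defines
the allowed values of an attribute; membership in that pool is the validity
check.  Values outside the pool are likely wrong or miscategorized.  Cross-
attribute constraint rules catch logical impossibilities (e.g. prostate
cancer recorded for a female patient), and discordance triage separates
systematic errors (concentrated in one study, correctable at the source) from
random ones.

Validation only emits findings; deciding what to change is the job of
:mod:`metaharm.consensus` and the curator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import is_na
from .ontology import OntologyGraph

__all__ = [
    "DynamicEnum",
    "ConstraintRule",
    "ValidationReport",
    "allowed_values",
    "validate_dynamic_enum",
    "check_constraints",
    "detect_systematic",
]


@dataclass
class DynamicEnum:
    """Allowed-value definition for one attribute.

    ``include_self`` controls whether the enum node itself is a legal value
    (by default only its descendants are).  ``allow_combinations`` permits
    multi-token cells whose every token is in the pool.
    """

    attribute: str
    enum_nodes: list
    include_self: bool = False
    allow_combinations: bool = True

    def __post_init__(self):
        if not self.enum_nodes:
            raise ValueError(f"{self.attribute}: enum_nodes must be non-empty")


@dataclass
class ConstraintRule:
    """If *if_attribute* takes one of *if_values*, *then_attribute* must not
    take any of *forbidden_values*.  NA never matches on either side."""

    id: str
    if_attribute: str
    if_values: set
    then_attribute: str
    forbidden_values: set

    def __post_init__(self):
        if self.if_attribute == self.then_attribute:
            raise ValueError(f"{self.id}: constraint attributes must be distinct")
        if not self.if_values or not self.forbidden_values:
            raise ValueError(f"{self.id}: value sets must be non-empty")
        self.if_values = {str(v).casefold() for v in self.if_values}
        self.forbidden_values = {str(v).casefold() for v in self.forbidden_values}


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def add(self, curation_id, attribute: str, token, kind: str, detail: str) -> None:
        assert kind in ("enum", "constraint", "roundtrip", "systematic")
        self.violations.append({"curation_id": curation_id, "attribute": attribute,
                                "token": token, "kind": kind, "detail": detail})

    def extend(self, other: "ValidationReport") -> None:
        self.violations.extend(other.violations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.violations,
                            columns=["curation_id", "attribute", "token", "kind", "detail"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def allowed_values(graph: OntologyGraph, enum: DynamicEnum) -> set:
    """Union of descendant closures of the enum nodes (CURIE pool)."""
    pool: set = set()
    for node in enum.enum_nodes:
        pool |= graph.relatives(node, "descendants", include_self=enum.include_self)
    return pool


def _allowed_labels(graph: OntologyGraph, pool: set) -> set:
    labels = set()
    for tid in pool:
        t = graph[tid]
        labels.add(t.label.strip().casefold())
        labels |= {s.strip().casefold() for s in t.synonyms}
    return labels


def validate_dynamic_enum(values: Sequence,
                          enum: DynamicEnum,
                          graph: OntologyGraph,
                          ids: Optional[Sequence] = None,
                          curation_ids: Optional[Sequence] = None,
                          delimiter: str = ";") -> ValidationReport:
    """Check each cell of a curated column against the enum's allowed pool.

    Tokens are validated by CURIE id when an aligned id column is given
    (ids are version-stable), falling back to case-folded label/synonym
    lookup.  Combination cells pass only when every token passes and the
    enum allows combinations.
    """
    pool = allowed_values(graph, enum)
    labels = _allowed_labels(graph, pool)
    report = ValidationReport()
    rids = curation_ids if curation_ids is not None else range(len(values))

    for rid, cell, cell_ids in zip(
            rids, values, ids if ids is not None else [None] * len(values)):
        if is_na(cell):
            continue
        tokens = [t.strip() for t in str(cell).split(delimiter) if t.strip()]
        tok_ids = ([t.strip() for t in str(cell_ids).split(delimiter)]
                   if cell_ids is not None and not is_na(cell_ids) else [None] * len(tokens))
        if len(tok_ids) != len(tokens):
            tok_ids = [None] * len(tokens)
        if len(tokens) > 1 and not enum.allow_combinations:
            report.add(rid, enum.attribute, cell, "enum",
                       "combination value where combinations are not allowed")
            continue
        for tok, tid in zip(tokens, tok_ids):
            if tid and tid != "NA":
                if tid not in pool:
                    report.add(rid, enum.attribute, tok, "enum",
                               f"id {tid} outside allowed pool")
            elif tok.casefold() not in labels:
                report.add(rid, enum.attribute, tok, "enum",
                           "label outside allowed pool")
    return report


def check_constraints(table: pd.DataFrame,
                      rules: Iterable[ConstraintRule],
                      curation_id_col: str = "curation_id",
                      delimiter: str = ";") -> ValidationReport:
    """Flag rows violating cross-attribute logical-consistency rules."""
    report = ValidationReport()
    for rule in rules:
        for col in (rule.if_attribute, rule.then_attribute):
            if col not in table.columns:
                raise KeyError(f"constraint {rule.id}: column absent: {col}")
        for idx, row in table.iterrows():
            cond, cons = row[rule.if_attribute], row[rule.then_attribute]
            if is_na(cond) or is_na(cons):
                continue
            cond_toks = {t.strip().casefold() for t in str(cond).split(delimiter)}
            cons_toks = {t.strip().casefold() for t in str(cons).split(delimiter)}
            if cond_toks & rule.if_values:
                bad = cons_toks & rule.forbidden_values
                for tok in sorted(bad):
                    rid = row[curation_id_col] if curation_id_col in table.columns else idx
                    report.add(rid, rule.then_attribute, tok, "constraint",
                               f"rule {rule.id}: {rule.if_attribute} in "
                               f"{sorted(rule.if_values)} forbids this value")
    return report


def detect_systematic(discordances: Iterable[dict],
                      threshold: float = 0.5) -> pd.DataFrame:
    """Triage discordances into systematic vs random errors by study share.

    *discordances* are records with at least a ``study`` key (e.g. one per
    sample whose annotations disagree across sources).  A study holding at
    least *threshold* of all discordances is flagged as a candidate
    systematic error — to be corrected at the source rather than row by row.

    Returns a frame with columns study, n, share, flagged, sorted by share
    descending; empty input yields an empty frame.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    records = list(discordances)
    cols = ["study", "n", "share", "flagged"]
    if not records:
        return pd.DataFrame(columns=cols)
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec["study"]] = counts.get(rec["study"], 0) + 1
    total = len(records)
    rows = [{"study": s, "n": n, "share": n / total, "flagged": n / total >= threshold}
            for s, n in counts.items()]
    return (pd.DataFrame(rows, columns=cols)
            .sort_values(["share", "study"], ascending=[False, True])
            .reset_index(drop=True))
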