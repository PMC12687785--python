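"""Conflict resolution across a patient's samples.

Attributes that cannot legitimately change over time (sex assigned at birth,
genetic ancestry) are reconciled by majority rule: the value appearing most
frequently among a patient's samples overwrites all of them; with no unique
plurality, every sample is set NA.  NA votes are excluded, so a patient with
one annotated and two missing samples gets the annotated value inferred for
all three.  The rule is deliberately restricted to time-invariant attributes
— applying it to dynamic clinical variables (disease stage, treatment status)
would destroy real longitudinal signal.

Granularity conflicts (the same concept annotated at different ontology
resolutions) are a separate mechanism: ancestor/descendant chains collapse to
the most specific term; incomparable siblings in a single-valued attribute
are irreconcilable and become NA with a conflict flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .model import is_na
from .ontology import OntologyGraph

__all__ = ["ConsensusDecision", "majority_consensus", "reconcile_granularity",
           "decisions_to_frame"]

# Per-patient outcome; precedence when rows mix fates:
# tied-NA > corrected > inferred > kept.
ACTIONS = ("kept", "inferred", "corrected", "tied-NA")


@dataclass
class ConsensusDecision:
    patient_id: str
    attribute: str
    chosen: Optional[str]
    votes: dict
    action: str
    affected_rows: list = field(default_factory=list)   # curation_ids that changed
    inferred_rows: list = field(default_factory=list)   # were NA, received chosen
    corrected_rows: list = field(default_factory=list)  # held a minority value

    def __post_init__(self):
        assert self.action in ACTIONS
        if self.chosen is not None and self.chosen not in self.votes:
            raise ValueError("chosen value must be one of the voted values or NA")


def majority_consensus(table: pd.DataFrame,
                       attribute: str,
                       patient_col: str,
                       time_invariant: bool,
                       curation_id_col: str = "curation_id") -> tuple:
    """Apply the majority rule per patient; returns (decisions, new column).

    The returned Series is aligned to *table* and holds the consensus value
    for every row.  The operation refuses attributes not declared
    time-invariant.
    """
    if not time_invariant:
        raise ValueError("consensus restricted to time-invariant attributes")
    for col in (attribute, patient_col):
        if col not in table.columns:
            raise KeyError(f"column absent from table: {col}")

    new = table[attribute].copy()
    decisions: list[ConsensusDecision] = []

    for patient, group in table.groupby(patient_col, sort=False):
        values = group[attribute]
        votes = Counter(v for v in values if not is_na(v))
        rids = (group[curation_id_col] if curation_id_col in group.columns
                else pd.Series(group.index, index=group.index))

        if not votes:
            decisions.append(ConsensusDecision(str(patient), attribute, None, {},
                                               "kept"))
            continue

        top = max(votes.values())
        winners = [v for v, n in votes.items() if n == top]

        if len(winners) > 1:  # tie among top counts → all rows NA
            affected = [rid for rid, v in zip(rids, values) if not is_na(v)]
            new.loc[group.index] = None
            decisions.append(ConsensusDecision(
                str(patient), attribute, None, dict(votes), "tied-NA",
                affected_rows=affected))
            continue

        chosen = winners[0]
        inferred = [rid for rid, v in zip(rids, values) if is_na(v)]
        corrected = [rid for rid, v in zip(rids, values)
                     if not is_na(v) and v != chosen]
        new.loc[group.index] = chosen
        action = "corrected" if corrected else ("inferred" if inferred else "kept")
        decisions.append(ConsensusDecision(
            str(patient), attribute, chosen, dict(votes), action,
            affected_rows=inferred + corrected,
            inferred_rows=inferred, corrected_rows=corrected))

    return decisions, new


def decisions_to_frame(decisions: Iterable[ConsensusDecision]) -> pd.DataFrame:
    """Audit log: one row per decision, suitable for TSV export."""
    rows = []
    for d in decisions:
        rows.append({
            "patient_id": d.patient_id, "attribute": d.attribute,
            "chosen": d.chosen if d.chosen is not None else "",
            "votes": ";".join(f"{v}={n}" for v, n in sorted(d.votes.items())),
            "action": d.action,
            "n_inferred": len(d.inferred_rows),
            "n_corrected": len(d.corrected_rows),
            "affected_rows": ";".join(str(r) for r in d.affected_rows),
        })
    return pd.DataFrame(rows, columns=["patient_id", "attribute", "chosen", "votes",
                                       "action", "n_inferred", "n_corrected",
                                       "affected_rows"])


def reconcile_granularity(values: Iterable[str],
                          graph: OntologyGraph,
                          multi_valued: bool = False) -> tuple:
    """Collapse a conflicting value set to its most specific terms.

    Ancestor/descendant chains resolve to the descendant.  For single-valued
    attributes, incomparable siblings that survive the collapse are a genuine
    conflict: the result is NA with the conflict flag set (the caller routes
    it to the validation report).  Multi-valued attributes keep all minimal
    terms.

    Returns ``(resolved set or None, conflict flag)``.
    """
    vals = set(values)
    if not vals:
        return None, False
    minimal = graph.most_specific(vals)
    if multi_valued or len(minimal) == 1:
        return minimal, False
    return None, True
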