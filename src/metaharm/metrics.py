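"""Harmonization quality metrics and merging-schema construction.

Four metrics summarize what harmonization bought:

compression
    number of original attributes merged into each curated attribute;
consolidation
    number of unique values per attribute (fewer after ontology mapping);
correction rate
    proportion of values updated during curation (only defined for
    one-to-one original→curated pairings);
completeness
    proportion of non-NA values per attribute.

The merging schema records the original→curated attribute mapping with
completeness and unique-value counts on both sides; it may be a function
(one-to-one/many-to-one) or a many-to-many relation, in which case the
correction rate is not applicable.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .etl import CleaningRules, clean_value
from .model import is_na

__all__ = [
    "attribute_metrics",
    "correction_rate",
    "compression",
    "build_merging_schema",
    "MERGING_SCHEMA_COLUMNS",
]

MERGING_SCHEMA_COLUMNS = [
    "original_field", "original_field_completeness", "original_field_unique_values",
    "curated_field", "curated_field_completeness", "curated_field_unique_values",
]


def attribute_metrics(column: Sequence, delimiter: str = ";",
                      mode: str = "cell") -> tuple:
    """(completeness, unique_values) of one column.

    Completeness is the non-NA fraction of cells.  Unique values are counted
    per whole cell by default (the merging-schema convention); ``mode='token'``
    splits on the delimiter first, so multi-valued cells contribute each
    distinct token.
    """
    if mode not in ("cell", "token"):
        raise ValueError(f"unknown counting mode: {mode!r}")
    values = list(column)
    if not values:
        raise ValueError("attribute_metrics requires a non-empty column")
    non_na = [v for v in values if not is_na(v)]
    completeness = len(non_na) / len(values)
    if mode == "cell":
        unique = len({str(v) for v in non_na})
    else:
        unique = len({t.strip() for v in non_na
                      for t in str(v).split(delimiter) if t.strip()})
    return completeness, unique


def correction_rate(original: Sequence, curated: Sequence,
                    many_to_many: bool = False,
                    rules: Optional[CleaningRules] = None,
                    attribute: str = "") -> Optional[float]:
    """Fraction of originally annotated values changed by curation.

    Compares the *cleaned* original cell with the curated cell (exact string
    inequality after trimming), over rows where the original is non-NA — so
    whitespace/NA normalization alone does not count as an update, only
    semantic replacement does.  Under a many-to-many original→curated plan a
    row-wise pairing does not exist and the measure is not applicable (NA).
    """
    if many_to_many:
        return None
    orig, cur = list(original), list(curated)
    if len(orig) != len(cur):
        raise ValueError(f"column length mismatch: {len(orig)} vs {len(cur)}")
    rules = rules or CleaningRules()
    changed = total = 0
    for o, c in zip(orig, cur):
        if is_na(o):
            continue
        total += 1
        cleaned = clean_value(o, attribute, rules)
        cur_s = None if is_na(c) else str(c).strip()
        if cleaned != cur_s:
            changed += 1
    if total == 0:
        return 0.0
    return changed / total


def compression(schema: pd.DataFrame) -> pd.Series:
    """Original attributes merged per curated attribute, from a merging schema."""
    return (schema.groupby("curated_field")["original_field"]
            .nunique().rename("compression"))


def build_merging_schema(edges: dict,
                         original: pd.DataFrame,
                         harmonized: pd.DataFrame,
                         delimiter: str = ";",
                         mode: str = "cell") -> pd.DataFrame:
    """Merging schema: one row per original→curated plan edge.

    *edges* maps curated attribute → list of original source columns.  The
    curated column is looked up as ``curated_{name}`` in *harmonized* (or as
    the bare name if no prefixed column exists).  Many-to-many plans simply
    repeat fields across rows — the long form used for repository metadata
    with many-to-many mapping relationships.
    """
    rows = []
    for curated, sources in edges.items():
        cur_col = f"curated_{curated}" if f"curated_{curated}" in harmonized.columns else curated
        if cur_col not in harmonized.columns:
            raise KeyError(f"curated column absent from harmonized table: {curated}")
        c_comp, c_uniq = attribute_metrics(harmonized[cur_col], delimiter, mode)
        for src in sources:
            if src not in original.columns:
                raise KeyError(f"original column absent from table: {src}")
            o_comp, o_uniq = attribute_metrics(original[src], delimiter, mode)
            rows.append({
                "original_field": src,
                "original_field_completeness": o_comp,
                "original_field_unique_values": o_uniq,
                "curated_field": curated,
                "curated_field_completeness": c_comp,
                "curated_field_unique_values": c_uniq,
            })
    return pd.DataFrame(rows, columns=MERGING_SCHEMA_COLUMNS)
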