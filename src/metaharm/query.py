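"""Hierarchy-aware querying and wide/long reshaping of harmonized tables.

``tree_filter`` searches a curated attribute with ontology awareness: a query
term matches not only its own label but all synonyms and every descendant
term's labels, synonyms and CURIEs.  Filtering by "ovarian carcinoma" thus
returns rows annotated with any subtype, which exact string matching would
miss.

``spread_meta``/``gather_meta`` transform between the sample-per-row wide
form and attribute-focused long forms: multi-valued cells explode to one row
per token; composite cells (``name:value`` pairs joined by ``;``) pivot to
one column per named feature.  The two are inverses up to canonical form
(first-appearance token order, duplicates removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import is_na
from .ontology import OntologyGraph

__all__ = ["QueryExpansion", "expand_query", "tree_filter",
           "spread_meta", "gather_meta", "canonical_multi"]


@dataclass
class QueryExpansion:
    """Match-key set derived from seed query terms.

    ``expanded`` holds case-folded match keys (labels, synonyms, CURIEs);
    ``provenance`` maps each key to why it is present: ``seed``, ``synonym``
    or ``descendant``.
    """

    seed_terms: list
    expanded: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def _add(self, key: str, reason: str) -> None:
        key = key.strip().casefold()
        if key and key not in self.provenance:
            self.expanded.add(key)
            self.provenance[key] = reason


def expand_query(graph: Optional[OntologyGraph], terms: Sequence[str]) -> QueryExpansion:
    """Expand query terms to labels, synonyms and all descendants.

    Terms may be labels, synonyms or CURIEs.  Unresolvable free-text terms
    contribute themselves verbatim (with a warning when nothing resolves), so
    the expansion is always a superset of the literal query.
    """
    exp = QueryExpansion(seed_terms=list(terms))
    resolved_any = False
    for term in terms:
        exp._add(str(term), "seed")
        if graph is None:
            continue
        if term in graph:
            tids = [term]
        else:
            tids = graph.resolve_label(str(term))
        if not tids:
            continue
        resolved_any = True
        for tid in tids:
            t = graph[tid]
            exp._add(tid, "seed")
            exp._add(t.label, "seed")
            for s in t.synonyms:
                exp._add(s, "synonym")
            for did in graph.descendants(tid):
                d = graph[did]
                exp._add(did, "descendant")
                exp._add(d.label, "descendant")
                for s in d.synonyms:
                    exp._add(s, "descendant")
    if graph is not None and terms and not resolved_any:
        warnings.warn(f"no query term resolved in the ontology: {list(terms)!r}",
                      stacklevel=2)
    return exp


def _cell_tokens(cell, delimiter: str) -> list:
    """Tokens of a cell; composite name:value pairs contribute the name part."""
    if is_na(cell):
        return []
    toks = []
    for t in str(cell).split(delimiter):
        t = t.strip()
        if not t:
            continue
        toks.append(t)
        if ":" in t:
            toks.append(t.split(":", 1)[0].strip())
    return toks


def tree_filter(table: pd.DataFrame,
                attribute: str,
                query: Sequence[str],
                graph: Optional[OntologyGraph] = None,
                logic: str = "any",
                delimiter: str = ";") -> pd.DataFrame:
    """Filter rows whose *attribute* cell matches the expanded query.

    ``logic='any'``: a row matches when at least one token hits the expansion
    of at least one query term.  ``logic='all'``: every query term's own
    expansion must be hit by at least one token.  Matching is case-folded
    against labels, synonyms and CURIEs; the paired
    ``{attribute}_ontology_term_id`` column, when present, contributes its
    tokens too.  NA cells never match; row order is preserved.
    """
    if logic not in ("any", "all"):
        raise ValueError(f"unknown logic: {logic!r}")
    if attribute not in table.columns:
        raise KeyError(f"unknown attribute: {attribute}")
    id_col = f"{attribute}_ontology_term_id"
    expansions = [expand_query(graph, [q]) for q in query]

    def row_tokens(row) -> set:
        toks = _cell_tokens(row[attribute], delimiter)
        if id_col in table.columns:
            toks += _cell_tokens(row[id_col], delimiter)
        return {t.casefold() for t in toks}

    keep = []
    for idx, row in table.iterrows():
        toks = row_tokens(row)
        if not toks:
            continue
        hits = [bool(toks & e.expanded) for e in expansions]
        if (logic == "any" and any(hits)) or (logic == "all" and all(hits)):
            keep.append(idx)
    return table.loc[keep]


# ---------------------------------------------------------------------------
# reshaping
# ---------------------------------------------------------------------------

def canonical_multi(cell, delimiter: str = ";"):
    """Canonical multi-valued cell: first-appearance order, duplicates removed."""
    if is_na(cell):
        return None
    out, seen = [], set()
    for t in str(cell).split(delimiter):
        t = t.strip()
        if t and t not in seen:
            seen.add(t)
            out.append(t)
    return delimiter.join(out) if out else None


def spread_meta(table: pd.DataFrame, attribute: str, kind: str,
                delimiter: str = ";") -> pd.DataFrame:
    """Long/wide expansion of a multi-valued or composite attribute.

    multi
        one output row per token, all other columns duplicated (curation_id
        is deliberately repeated across the expanded rows); token order
        preserved; NA cells yield a single row with NA.
    composite
        one new column ``{attribute}_{name}`` per distinct feature name of
        the ``name:value`` pairs; absent names are NA; the composite column
        itself is dropped.

    Idempotent on already-spread input.  The spread state is recorded in
    ``result.attrs['spread']``.
    """
    if kind not in ("multi", "composite"):
        raise ValueError(f"spread_meta requires kind multi or composite, got {kind!r}")
    if attribute not in table.columns:
        raise KeyError(f"unknown attribute: {attribute}")

    if kind == "multi":
        rows = []
        for _, row in table.iterrows():
            cell = row[attribute]
            tokens = ([t.strip() for t in str(cell).split(delimiter) if t.strip()]
                      if not is_na(cell) else [None])
            for tok in tokens or [None]:
                r = row.copy()
                r[attribute] = tok
                rows.append(r)
        out = pd.DataFrame(rows).reset_index(drop=True)
        out = out[table.columns]
    else:
        names: list[str] = []
        parsed: list[dict] = []
        bad: list = []
        for idx, row in table.iterrows():
            cell = row[attribute]
            features: dict[str, str] = {}
            if not is_na(cell):
                for tok in str(cell).split(delimiter):
                    tok = tok.strip()
                    if not tok:
                        continue
                    if ":" not in tok:
                        rid = row.get("curation_id", idx)
                        bad.append(rid)
                        continue
                    name, value = tok.split(":", 1)
                    name = name.strip()
                    if name not in features:  # first pair wins
                        features[name] = value.strip()
                    if name not in names:
                        names.append(name)
            parsed.append(features)
        if bad:
            raise ValueError(f"malformed composite token (no ':') in rows: {bad}")
        out = table.drop(columns=[attribute]).reset_index(drop=True)
        for name in names:
            out[f"{attribute}_{name}"] = [f.get(name) for f in parsed]
    out.attrs["spread"] = {"attribute": attribute, "kind": kind,
                           "delimiter": delimiter}
    return out


def gather_meta(table: pd.DataFrame, attribute: str, kind: str,
                delimiter: str = ";",
                key: str = "curation_id") -> pd.DataFrame:
    """Inverse of :func:`spread_meta` up to canonical form.

    multi
        rows sharing *key* collapse back to one row with tokens joined in
        first-appearance order; context columns that disagree within a group
        make the gather non-rectangular and raise.
    composite
        columns ``{attribute}_{name}`` collapse to ``name:value`` pairs in
        column order, skipping NA values.
    """
    if kind not in ("multi", "composite"):
        raise ValueError(f"gather_meta requires kind multi or composite, got {kind!r}")

    if kind == "multi":
        if attribute not in table.columns:
            raise KeyError(f"unknown attribute: {attribute}")
        if key not in table.columns:
            raise KeyError(f"gather key column absent: {key}")
        context = [c for c in table.columns if c not in (attribute,)]
        rows = []
        for _, group in table.groupby(key, sort=False):
            for col in context:
                vals = group[col]
                distinct = {("NA" if is_na(v) else str(v)) for v in vals}
                if len(distinct) > 1:
                    raise ValueError(
                        f"non-rectangular gather: column {col!r} disagrees within "
                        f"{key}={group[key].iloc[0]!r}")
            r = group.iloc[0].copy()
            toks = [t for t in group[attribute] if not is_na(t)]
            r[attribute] = canonical_multi(delimiter.join(str(t) for t in toks),
                                           delimiter) if toks else None
            rows.append(r)
        out = pd.DataFrame(rows).reset_index(drop=True)[table.columns]
    else:
        prefix = f"{attribute}_"
        feat_cols = [c for c in table.columns if c.startswith(prefix)]
        # an all-NA composite spreads to zero feature columns; gather then
        # reconstructs an all-NA attribute
        cells = []
        for _, row in table.iterrows():
            pairs = [f"{c[len(prefix):]}:{row[c]}" for c in feat_cols
                     if not is_na(row[c])]
            cells.append(delimiter.join(pairs) if pairs else None)
        out = table.drop(columns=feat_cols).reset_index(drop=True)
        out[attribute] = cells
    out.attrs.pop("spread", None)
    return out
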