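"""The ETL transform: value cleaning, numeric/unit splitting, curation maps.

The transform source of truth is the per-attribute curation map — a lookup
from observed original values to curated ontology terms with CURIE ids and
source-ontology prefixes, authored by curators (this package never infers
mappings).  Map keys are normalized by trim + casefold only: the core path is
deterministic, with no fuzzy matching.

The cleaning pass that precedes mapping handles the recurring legacy-metadata
pathologies: NA-equivalent tokens, delimiter aliases, attribute-specific
binary (yes/no) encodings, and curator-defined abbreviations.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from difflib import get_close_matches
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd
import yaml

from .model import is_na
from .ontology import OntologyGraph, curie_prefix

__all__ = [
    "CleaningRules",
    "CurationMapEntry",
    "CurationMap",
    "clean_value",
    "split_numeric_unit",
    "split_numeric_range",
    "apply_curation_map",
    "harmonize_attribute",
    "harmonize_table",
    "unmapped_report",
    "DEFAULT_NA_LEXICON",
]

# "Unknown" is deliberately absent: it is a legitimate curated value for e.g.
# vital status.  The lexicon is configuration, not a constant of the method.
DEFAULT_NA_LEXICON = frozenset({"", "na", "n/a", "not available", "not provided", "-"})


def _normkey(s: str) -> str:
    return str(s).strip().casefold()


@dataclass
class CleaningRules:
    """Configurable value-cleaning lexicons.

    ``binary_map`` keys are ``(attribute, token)`` pairs (token case-folded):
    presence/absence encodings like ``antibiotics=yes`` become descriptive
    values.  ``delimiter_aliases`` are characters normalized to ``;``.
    """

    na_lexicon: frozenset = DEFAULT_NA_LEXICON
    binary_map: dict = field(default_factory=dict)
    delimiter_aliases: frozenset = frozenset({",", "|"})
    abbreviation_lexicon: dict = field(default_factory=dict)

    def __post_init__(self):
        self.na_lexicon = frozenset(_normkey(t) for t in self.na_lexicon)
        self.binary_map = {(a, _normkey(t)): v for (a, t), v in self.binary_map.items()}
        self.abbreviation_lexicon = {_normkey(k): v
                                     for k, v in self.abbreviation_lexicon.items()}

    @classmethod
    def from_config(cls, path) -> "CleaningRules":
        """Load from YAML/JSON: na_lexicon, binary_map, abbreviation_lexicon,
        delimiter_aliases.  binary_map nests attribute → token → value."""
        with open(path) as fh:
            cfg = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
        cfg = cfg or {}
        binary = {}
        for attr, tokens in (cfg.get("binary_map") or {}).items():
            for tok, val in tokens.items():
                binary[(attr, tok)] = val
        return cls(
            na_lexicon=frozenset(cfg.get("na_lexicon", DEFAULT_NA_LEXICON)),
            binary_map=binary,
            delimiter_aliases=frozenset(cfg.get("delimiter_aliases", {",", "|"})),
            abbreviation_lexicon=dict(cfg.get("abbreviation_lexicon", {})),
        )


def clean_value(raw, attribute: str, rules: Optional[CleaningRules] = None):
    """Clean one cell; returns a string or NA (None), never raises on text.

    Trims whitespace, maps empty strings and NA-lexicon hits to NA, normalizes
    delimiter aliases to ``;``, then token-wise applies the binary map (keyed
    by attribute) and the abbreviation lexicon.
    """
    if rules is None:
        rules = CleaningRules()
    if is_na(raw):
        return None
    s = str(raw).strip()
    if _normkey(s) in rules.na_lexicon:
        return None
    for alias in rules.delimiter_aliases:
        s = s.replace(alias, ";")
    out = []
    for tok in s.split(";"):
        tok = tok.strip()
        key = _normkey(tok)
        if key in rules.na_lexicon:
            continue
        tok = rules.binary_map.get((attribute, key), tok)
        tok = rules.abbreviation_lexicon.get(_normkey(tok), tok)
        if tok:
            out.append(tok)
    return ";".join(out) if out else None


class NumericSplit(NamedTuple):
    value: Optional[float]
    unit: Optional[str]
    flagged: bool


_NUMERIC_RE = re.compile(r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(.*?)\s*$")


def split_numeric_unit(raw) -> NumericSplit:
    """Split ``"34 years"`` into (34.0, "years"); pure numbers get unit NA.

    A cell with no parseable numeric prefix yields (NA, NA) with ``flagged``
    set — callers collect flagged cells for curator review instead of
    receiving an exception.
    """
    if is_na(raw):
        raise ValueError("split_numeric_unit requires a non-NA cell")
    m = _NUMERIC_RE.match(str(raw))
    if not m:
        return NumericSplit(None, None, True)
    value = float(m.group(1))
    unit = m.group(2) or None
    return NumericSplit(value, unit, False)


_RANGE_RE = re.compile(r"^\s*(\d+\.?\d*)\s*[-–]\s*(\d+\.?\d*)\s*$")


def split_numeric_range(raw) -> tuple:
    """Optional range split for censored/binned numerics → (min, max).

    ``">89"`` → (89, NA), ``"<5"`` → (NA, 5), ``"40-49"`` → (40, 49).
    Anything else → (NA, NA); combine with :func:`split_numeric_unit` flags.
    """
    if is_na(raw):
        return (None, None)
    s = str(raw).strip()
    if s.startswith(">"):
        sp = split_numeric_unit(s[1:].lstrip("="))
        return (sp.value, None)
    if s.startswith("<"):
        sp = split_numeric_unit(s[1:].lstrip("="))
        return (None, sp.value)
    m = _RANGE_RE.match(s)
    if m:
        return (float(m.group(1)), float(m.group(2)))
    return (None, None)


# ---------------------------------------------------------------------------
# curation maps
# ---------------------------------------------------------------------------

@dataclass
class CurationMapEntry:
    original_value: str
    curated_ontology_term: str
    curated_ontology_term_id: Optional[str] = None
    curated_ontology_term_db: Optional[str] = None

    def __post_init__(self):
        if not str(self.original_value).strip():
            raise ValueError("curation-map original_value empty after trimming")
        tid, db = self.curated_ontology_term_id, self.curated_ontology_term_db
        if tid and db and curie_prefix(tid) != db:
            raise ValueError(f"map entry {self.original_value!r}: "
                             f"id prefix {curie_prefix(tid)!r} != db {db!r}")


class CurationMap:
    """Per-attribute ``original value → ontology term`` dictionary.

    Keys are normalized (trim + casefold) and must be unique after
    normalization.  A literal ``;`` inside an original value is unsupported
    (it is the multi-value delimiter) and rejected at load.
    """

    FIELDS = ["original_value", "curated_ontology_term",
              "curated_ontology_term_id", "curated_ontology_term_db"]

    def __init__(self, attribute: str, entries: Iterable[CurationMapEntry]):
        self.attribute = attribute
        self.entries: dict[str, CurationMapEntry] = {}
        for e in entries:
            if ";" in e.original_value:
                raise ValueError(
                    f"{attribute}: original_value {e.original_value!r} contains ';' "
                    "(escaping not supported)")
            key = _normkey(e.original_value)
            if key in self.entries:
                raise ValueError(f"{attribute}: duplicate normalized key {key!r}")
            self.entries[key] = e

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, token: str) -> Optional[CurationMapEntry]:
        return self.entries.get(_normkey(token))

    @classmethod
    def identity(cls, attribute: str) -> "CurationMap":
        return cls(attribute, [])

    @classmethod
    def from_csv(cls, path, attribute: Optional[str] = None) -> "CurationMap":
        import os
        name = attribute or os.path.splitext(os.path.basename(str(path)))[0]
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in cls.FIELDS if c not in df.columns]
        if missing:
            raise ValueError(f"curation map {path}: missing columns {missing}")
        entries = [CurationMapEntry(
            original_value=row["original_value"],
            curated_ontology_term=row["curated_ontology_term"],
            curated_ontology_term_id=row["curated_ontology_term_id"] or None,
            curated_ontology_term_db=row["curated_ontology_term_db"] or None,
        ) for _, row in df.iterrows()]
        return cls(name, entries)

    def to_csv(self, path) -> None:
        rows = [{"original_value": e.original_value,
                 "curated_ontology_term": e.curated_ontology_term,
                 "curated_ontology_term_id": e.curated_ontology_term_id or "",
                 "curated_ontology_term_db": e.curated_ontology_term_db or ""}
                for e in self.entries.values()]
        pd.DataFrame(rows, columns=self.FIELDS).to_csv(path, index=False)


class MappedCell(NamedTuple):
    terms: Optional[str]     # delimited curated terms, or NA
    ids: Optional[str]       # aligned CURIEs ("NA" placeholder), or NA
    dbs: Optional[str]       # aligned ontology prefixes, or NA
    unmapped: list           # tokens with no map entry


def apply_curation_map(cell, cmap: CurationMap, delimiter: str = ";",
                       unmapped: str = "passthrough") -> MappedCell:
    """Map each delimited token of *cell* through the curation map.

    Mapped tokens are replaced by their curated terms; duplicates arising
    after mapping (e.g. two brand names of one generic drug) are collapsed
    keeping first-occurrence order, with ids/dbs kept aligned to the surviving
    terms.  Unmapped tokens are reported and either passed through
    (``unmapped='passthrough'``) or dropped to NA (``'na'``).
    """
    if unmapped not in ("passthrough", "na"):
        raise ValueError(f"unknown unmapped policy: {unmapped!r}")
    if is_na(cell):
        return MappedCell(None, None, None, [])
    terms: list[str] = []
    ids: list[str] = []
    dbs: list[str] = []
    missing: list[str] = []
    seen: set[str] = set()
    for token in str(cell).split(delimiter):
        token = token.strip()
        if not token:
            continue
        entry = cmap.lookup(token)
        if entry is None:
            missing.append(token)
            if unmapped == "na":
                continue
            term, tid, db = token, None, None
        else:
            term, tid, db = (entry.curated_ontology_term,
                             entry.curated_ontology_term_id,
                             entry.curated_ontology_term_db)
        key = _normkey(term)
        if key in seen:
            continue
        seen.add(key)
        terms.append(term)
        ids.append(tid or "NA")
        dbs.append(db or "NA")
    if not terms:
        return MappedCell(None, None, None, missing)
    joined_ids = delimiter.join(ids) if any(i != "NA" for i in ids) else None
    joined_dbs = delimiter.join(dbs) if any(d != "NA" for d in dbs) else None
    return MappedCell(delimiter.join(terms), joined_ids, joined_dbs, missing)


# ---------------------------------------------------------------------------
# per-attribute harmonization
# ---------------------------------------------------------------------------

def harmonize_attribute(table: pd.DataFrame,
                        curated_name: str,
                        sources: Sequence[str],
                        maps: dict,
                        rules: Optional[CleaningRules] = None,
                        graph: Optional[OntologyGraph] = None,
                        kind: str = "multi",
                        delimiter: str = ";",
                        unmapped: str = "passthrough") -> tuple:
    """Pool, clean and map *sources* into one curated attribute with provenance.

    Per row, each source cell is cleaned then mapped through that source's
    curation map; non-NA results are pooled in plan order and de-duplicated.
    When a graph is given and ids are available, values annotated at several
    resolutions collapse to the most specific term.  For single-valued
    attributes, irreconcilable multi-value rows are set NA and routed to the
    returned conflict list — never silently dropped.

    Returns ``(frame, conflicts)`` where *frame* holds the four provenance
    columns (``curated_X``, ``curated_X_ontology_term_id``,
    ``curated_X_source``, ``original_X_value``) aligned to *table*.
    """
    rules = rules or CleaningRules()
    for src in sources:
        if src not in table.columns:
            raise KeyError(f"source column absent from table: {src}")
        if src not in maps and unmapped != "passthrough":
            raise ValueError(f"no curation map for source {src!r} "
                             "and pass-through not configured")

    out = {f"curated_{curated_name}": [], f"curated_{curated_name}_ontology_term_id": [],
           f"curated_{curated_name}_source": [], f"original_{curated_name}_value": []}
    conflicts = []

    for idx, row in table.iterrows():
        terms: list[str] = []
        ids: list[Optional[str]] = []
        used_sources: list[str] = []
        originals: list[str] = []
        seen: set[str] = set()
        for src in sources:
            raw = row[src]
            cleaned = clean_value(raw, src, rules)
            if cleaned is None:
                continue
            cmap = maps.get(src) or CurationMap.identity(src)
            mapped = apply_curation_map(cleaned, cmap, delimiter, unmapped)
            if mapped.terms is None:
                continue
            toks = mapped.terms.split(delimiter)
            tok_ids = (mapped.ids.split(delimiter) if mapped.ids
                       else ["NA"] * len(toks))
            contributed = False
            for term, tid in zip(toks, tok_ids):
                key = _normkey(term)
                if key in seen:
                    continue
                seen.add(key)
                terms.append(term)
                ids.append(None if tid == "NA" else tid)
                contributed = True
            if contributed or mapped.terms is not None:
                used_sources.append(src)
                originals.append(str(raw).strip())

        if graph is not None and len(terms) > 1:
            terms, ids = _reduce_most_specific(terms, ids, graph)

        if kind == "single" and len(terms) > 1:
            conflicts.append({"row": idx, "attribute": curated_name,
                              "values": list(terms),
                              "sources": list(used_sources)})
            terms, ids = [], []

        out[f"curated_{curated_name}"].append(delimiter.join(terms) if terms else None)
        out[f"curated_{curated_name}_ontology_term_id"].append(
            delimiter.join(i or "NA" for i in ids)
            if any(i for i in ids) else None)
        out[f"curated_{curated_name}_source"].append(
            delimiter.join(used_sources) if used_sources else None)
        out[f"original_{curated_name}_value"].append(
            delimiter.join(originals) if originals else None)

    frame = pd.DataFrame(out, index=table.index)
    return frame, conflicts


def _reduce_most_specific(terms: list, ids: list, graph: OntologyGraph) -> tuple:
    """Drop terms whose id is a strict ancestor of another term's id."""
    with_ids = {tid for tid in ids if tid and tid in graph}
    if len(with_ids) < 2:
        return terms, ids
    keep_ids = graph.most_specific(with_ids)
    keep_t, keep_i = [], []
    for term, tid in zip(terms, ids):
        if tid and tid in graph and tid not in keep_ids:
            continue
        keep_t.append(term)
        keep_i.append(tid)
    return keep_t, keep_i


def harmonize_table(table: pd.DataFrame,
                    edges: dict,
                    maps: dict,
                    rules: Optional[CleaningRules] = None,
                    graph: Optional[OntologyGraph] = None,
                    kinds: Optional[dict] = None,
                    delimiter: str = ";",
                    unmapped: str = "passthrough") -> tuple:
    """Harmonize every curated attribute of a merge plan.

    *edges* maps curated attribute → ordered source columns; *kinds* maps
    curated attribute → structural kind (default ``multi``).  Returns
    ``(harmonized frame, conflicts)`` with provenance columns for every
    attribute, in plan order.
    """
    frames, conflicts = [], []
    for curated, sources in edges.items():
        kind = (kinds or {}).get(curated, "multi")
        frame, conf = harmonize_attribute(table, curated, sources, maps, rules,
                                          graph, kind, delimiter, unmapped)
        frames.append(frame)
        conflicts.extend(conf)
    out = pd.concat(frames, axis=1) if frames else pd.DataFrame(index=table.index)
    return out, conflicts


def unmapped_report(table: pd.DataFrame,
                    edges: dict,
                    maps: dict,
                    rules: Optional[CleaningRules] = None,
                    delimiter: str = ";",
                    suggest: bool = False) -> pd.DataFrame:
    """Curator work-queue: distinct cleaned tokens lacking a map entry.

    One row per (curated attribute, source, token) with its occurrence count,
    sorted descending by count.  ``suggest=True`` adds the closest existing
    map value by edit similarity (a hint only — the mapping path itself never
    fuzzy-matches).
    """
    rules = rules or CleaningRules()
    counts: dict[tuple, int] = {}
    for curated, sources in edges.items():
        for src in sources:
            if src not in table.columns:
                raise KeyError(f"source column absent from table: {src}")
            cmap = maps.get(src) or CurationMap.identity(src)
            for raw in table[src]:
                cleaned = clean_value(raw, src, rules)
                if cleaned is None:
                    continue
                for tok in cleaned.split(delimiter):
                    tok = tok.strip()
                    if tok and cmap.lookup(tok) is None:
                        counts[(curated, src, tok)] = counts.get((curated, src, tok), 0) + 1
    rows = [{"attribute": a, "source": s, "value": v, "count": n}
            for (a, s, v), n in counts.items()]
    df = pd.DataFrame(rows, columns=["attribute", "source", "value", "count"])
    df = df.sort_values(["count", "attribute", "source", "value"],
                        ascending=[False, True, True, True]).reset_index(drop=True)
    if suggest and len(df):
        vocab = sorted({e.curated_ontology_term
                        for m in maps.values() for e in m.entries.values()})
        df["suggestion"] = [
            (get_close_matches(v, vocab, n=1) or [""])[0] for v in df["value"]]
    return df
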