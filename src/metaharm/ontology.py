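"""In-memory ontology DAG: traversal, label resolution, round-trip validation.

Terms are identified by CURIEs (``PREFIX:LOCAL``, e.g. ``HANCESTRO:0004``) and
linked by ``is_a`` edges only.  A graph may hold several ontology prefixes as
disjoint components; cross-ontology edges are never inferred.  Cycles are a
load-time error.  OWL reasoning and live lookup services are out of scope —
the graph is an offline snapshot.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "SharedAncestors",
    "read_obo",
    "read_term_table",
]

_CURIE_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_.-]*):(\S+)$")
# obonet keeps synonym tags verbatim, e.g. '"ACE inhibitor" EXACT []'
_SYNONYM_RE = re.compile(r'"([^"]+)"')


def curie_prefix(curie: str) -> str:
    m = _CURIE_RE.match(curie)
    if not m:
        raise ValueError(f"not a CURIE: {curie!r}")
    return m.group(1)


@dataclass
class OntologyTerm:
    """One ontology class: CURIE id, display label, synonyms and parents."""

    id: str
    label: str
    synonyms: set = field(default_factory=set)
    parents: set = field(default_factory=set)
    db: str = ""
    obsolete: bool = False

    def __post_init__(self):
        prefix = curie_prefix(self.id)
        if not self.db:
            self.db = prefix
        elif self.db != prefix:
            raise ValueError(f"{self.id}: db {self.db!r} != CURIE prefix {prefix!r}")
        self.synonyms = set(self.synonyms)
        self.parents = set(self.parents)


class SharedAncestors(NamedTuple):
    """Ancestor intersection of a term set plus its most-specific members."""
    all: frozenset
    minimal: frozenset


class OntologyGraph:
    """DAG of :class:`OntologyTerm` with child→parent ``is_a`` edges.

    Parent CURIEs absent from the term set are recorded as *dangling* rather
    than rejected, so partial snapshots load; dangling ids never appear in
    traversal results.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise ValueError(f"duplicate term id: {t.id}")
            self.terms[t.id] = t
        self.dangling: set[str] = set()
        self._children: dict[str, set] = {tid: set() for tid in self.terms}
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                if p in self.terms:
                    self._children[p].add(t.id)
                    g.add_edge(t.id, p)
                else:
                    self.dangling.add(p)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"cycle detected in is_a hierarchy: {cyc}")
        # label/synonym index, case-folded, built lazily on first resolve
        self._label_index: Optional[dict[str, list]] = None

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise KeyError(f"term not found: {term_id}") from None

    def children(self, term_id: str) -> set:
        self[term_id]
        return set(self._children[term_id])

    # ---- traversal ------------------------------------------------------

    def relatives(self, node: str, direction: str = "descendants",
                  include_self: bool = False, include_obsolete: bool = False) -> set:
        """Transitive closure along ``is_a`` edges.

        ``direction='descendants'`` walks child edges, ``'ancestors'`` walks
        parent edges.  Obsolete terms are excluded from the result by default;
        they are still traversed through, so marking an internal node obsolete
        does not hide its subtree.
        """
        if direction not in ("descendants", "ancestors"):
            raise ValueError(f"unknown direction: {direction!r}")
        self[node]
        step = (self._children.__getitem__ if direction == "descendants"
                else lambda i: self.terms[i].parents & self.terms.keys())
        seen: set = set()
        stack = [node]
        while stack:
            for nxt in step(stack.pop()):
                if nxt not in seen and nxt != node:
                    seen.add(nxt)
                    stack.append(nxt)
        if not include_obsolete:
            seen = {i for i in seen if not self.terms[i].obsolete}
        if include_self:
            seen.add(node)
        return seen

    def descendants(self, node: str, include_self: bool = False,
                    include_obsolete: bool = False) -> set:
        return self.relatives(node, "descendants", include_self, include_obsolete)

    def ancestors(self, node: str, include_self: bool = False,
                  include_obsolete: bool = False) -> set:
        return self.relatives(node, "ancestors", include_self, include_obsolete)

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff *a* is a strict ancestor of *b*."""
        return a in self.relatives(b, "ancestors", include_obsolete=True)

    # ---- label resolution -----------------------------------------------

    def _index(self) -> dict[str, list]:
        if self._label_index is None:
            idx: dict[str, list] = {}
            for t in self.terms.values():
                if t.obsolete:
                    continue
                idx.setdefault(t.label.strip().casefold(), []).append((0, t.id))
                for s in t.synonyms:
                    idx.setdefault(s.strip().casefold(), []).append((1, t.id))
            self._label_index = idx
        return self._label_index

    def resolve_label(self, text: str, prefix_order: Optional[Sequence[str]] = None) -> list:
        """CURIEs whose label or synonym equals *text* after trim+casefold.

        Exact label matches rank before synonym matches; ties within a rank
        follow *prefix_order* when given, else graph load order.  Returns an
        empty list when nothing matches.
        """
        if not text or not str(text).strip():
            return []
        hits = self._index().get(str(text).strip().casefold(), [])
        if prefix_order:
            rank = {p: i for i, p in enumerate(prefix_order)}
            key = lambda h: (h[0], rank.get(curie_prefix(h[1]), len(rank)))
            hits = sorted(hits, key=key)
        else:
            hits = sorted(hits, key=lambda h: h[0])
        out, seen = [], set()
        for _, tid in hits:
            if tid not in seen:
                seen.add(tid)
                out.append(tid)
        return out

    # ---- round-trip validation -------------------------------------------

    def roundtrip_validate(self, entries: Iterable[tuple]) -> list:
        """Resolve each (term, CURIE) pair back through the graph.

        For every entry the CURIE is looked up and the stored label/synonyms
        are compared (case-insensitively) with the given term.  Mismatch
        records carry ``{id, given, found, reason}`` with reason one of
        ``unknown-id``, ``label-mismatch``, ``obsolete``.
        """
        mismatches = []
        for term, tid in entries:
            if tid not in self.terms:
                mismatches.append({"id": tid, "given": term, "found": None,
                                   "reason": "unknown-id"})
                continue
            t = self.terms[tid]
            if t.obsolete:
                mismatches.append({"id": tid, "given": term, "found": t.label,
                                   "reason": "obsolete"})
                continue
            names = {t.label.strip().casefold()} | {s.strip().casefold() for s in t.synonyms}
            if str(term).strip().casefold() not in names:
                mismatches.append({"id": tid, "given": term, "found": t.label,
                                   "reason": "label-mismatch"})
        return mismatches

    # ---- set operations ---------------------------------------------------

    def most_specific(self, values: Iterable[str]) -> set:
        """Drop every value that is a strict ancestor of another value.

        Implements consolidation to the most specific information when the
        same concept is annotated at several resolutions.  Unrelated values
        are all retained; idempotent.
        """
        vals = set(values)
        for v in vals:
            self[v]
        drop = set()
        for v in vals:
            anc = self.relatives(v, "ancestors", include_obsolete=True)
            drop |= anc & vals
        return vals - drop

    def shared_ancestors(self, values: Iterable[str]) -> SharedAncestors:
        """Intersection of ancestor closures (self included) of *values*.

        The ``minimal`` member marks the most specific shared ancestors —
        no marked member is a strict ancestor of another marked member.
        Values from disjoint roots yield an empty result (not an error).
        This is the search used to pick dynamic-enum candidate nodes.
        """
        vals = list(values)
        if not vals:
            raise ValueError("shared_ancestors requires a non-empty value set")
        shared: Optional[set] = None
        for v in vals:
            closure = self.relatives(v, "ancestors", include_self=True,
                                     include_obsolete=True)
            shared = closure if shared is None else shared & closure
        assert shared is not None
        minimal = self.most_specific(shared) if shared else set()
        return SharedAncestors(frozenset(shared), frozenset(minimal))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_obo(path) -> OntologyGraph:
    """Load an OBO file (id, name, is_a, synonym, is_obsolete tags)."""
    g = obonet.read_obo(path, ignore_obsolete=False)
    terms = []
    for tid, data in g.nodes(data=True):
        if not _CURIE_RE.match(tid):
            continue
        synonyms = set()
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.search(raw)
            synonyms.add(m.group(1) if m else raw)
        terms.append(OntologyTerm(
            id=tid,
            label=data.get("name", tid),
            synonyms=synonyms,
            parents=set(data.get("is_a", [])),
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
        ))
    return OntologyGraph(terms)


def read_term_table(path) -> OntologyGraph:
    """Load a flat term table: CSV with id, label, parents, synonyms, obsolete.

    ``parents`` and ``synonyms`` are pipe-delimited; ``obsolete`` is optional.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    terms = []
    for _, row in df.iterrows():
        terms.append(OntologyTerm(
            id=row["id"],
            label=row["label"],
            synonyms={s for s in row.get("synonyms", "").split("|") if s},
            parents={p for p in row.get("parents", "").split("|") if p},
            obsolete=str(row.get("obsolete", "")).strip().lower() in ("true", "1", "yes"),
        ))
    return OntologyGraph(terms)
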