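"""Synthetic ontologies and messy metadata cohorts with known ground truth.

Every corruption the generator injects mirrors a quality issue recurrent in
legacy repository metadata: typos, curator-defined abbreviations and brand
names, binary (yes/no) re-encodings of categorical values, one concept
dispersed across several sparse columns, values misplaced under the wrong
attribute, and conflicting annotations across a patient's samples.

The generator emits, alongside the messy table, the *oracle* curation maps
needed to undo the recoverable corruptions and a log of the unrecoverable
ones.  Typos and misplacements are deliberately excluded from the oracle
maps — they stand in for errors that only manual review fixes — so recovery
tests measure the map-driven pipeline, not magic.  All outputs are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import majority_consensus
from .etl import CleaningRules, CurationMap, CurationMapEntry, harmonize_table
from .model import AttributeSpec, add_curation_ids, is_na
from .ontology import OntologyGraph, OntologyTerm
from .query import canonical_multi

__all__ = [
    "CorruptionConfig",
    "CorruptionResult",
    "make_toy_ontology",
    "make_clean_cohort",
    "corrupt_metadata",
    "recover_cohort",
    "recovery_report",
]


@dataclass
class CorruptionConfig:
    """Rates and structure of the injected mess.

    Defaults reflect a plausibly messy legacy cohort: aliases/abbreviations
    are the dominant problem, typos and misplacements are rare, one patient
    in five carries a conflicting annotation, and one attribute is dispersed
    over three sparse columns.
    """

    typo_rate: float = 0.02
    abbreviation_rate: float = 0.30
    binary_encode_rate: float = 0.15
    dispersal_columns: int = 3
    misplacement_rate: float = 0.02
    conflict_rate: float = 0.20
    seed: int = 0

    def __post_init__(self):
        for name in ("typo_rate", "abbreviation_rate", "binary_encode_rate",
                     "misplacement_rate", "conflict_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.dispersal_columns < 1:
            raise ValueError("dispersal_columns must be >= 1")


# ---------------------------------------------------------------------------
# toy ontology
# ---------------------------------------------------------------------------

def make_toy_ontology(depth: int = 3, branching: int = 3,
                      prefixes: Sequence[str] = ("TOY",), seed: int = 0,
                      synonym_rate: float = 0.3,
                      multiparent_rate: float = 0.1) -> tuple:
    """Deterministic rooted DAG per prefix; returns (graph, leaf ids).

    Level *d* holds ``branching**d`` terms, so one prefix yields
    ``sum(branching**d for d in 0..depth)`` terms.  A seeded fraction of
    non-root terms receive a synonym and a second parent drawn from the
    previous level (edges only point to earlier levels, so acyclicity is
    structural).
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    terms: list[OntologyTerm] = []
    leaves: list[str] = []
    for prefix in prefixes:
        counter = 0

        def make_id():
            nonlocal counter
            counter += 1
            return f"{prefix}:{counter:07d}"

        root = OntologyTerm(make_id(), f"{prefix.lower()} root")
        terms.append(root)
        level = [root]
        for d in range(depth):
            nxt = []
            for parent in level:
                for b in range(branching):
                    tid = make_id()
                    t = OntologyTerm(tid, f"{prefix.lower()} term {counter}",
                                     parents={parent.id})
                    if rng.random() < synonym_rate:
                        t.synonyms.add(f"{t.label} (syn)")
                    if d > 0 and len(level) > 1 and rng.random() < multiparent_rate:
                        other = level[rng.integers(len(level))]
                        t.parents.add(other.id)
                    terms.append(t)
                    nxt.append(t)
            level = nxt
        leaves.extend(t.id for t in level)
    return OntologyGraph(terms), leaves


# ---------------------------------------------------------------------------
# clean cohort
# ---------------------------------------------------------------------------

_WORDS = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta"]


def make_clean_cohort(n_patients: int,
                      samples_per_patient: int,
                      attributes: Sequence[AttributeSpec],
                      graph: Optional[OntologyGraph],
                      seed: int = 0,
                      study_name: str = "synth01",
                      time_invariant: Sequence[str] = ("sex", "ancestry")) -> tuple:
    """Ground-truth cohort table; returns (table, patient_truth).

    Ontology-categorical values are drawn uniformly from the leaves under the
    attribute's dynamic-enum nodes (multi-valued attributes draw 1–3 tokens);
    time-invariant attributes are constant within a patient; numeric
    attributes come with units.  ``patient_truth`` records the per-patient
    value of each time-invariant attribute.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    allowed: dict[str, list] = {}
    for spec in attributes:
        if spec.value_class == "ontology-categorical":
            if graph is None or not spec.dynamic_enum_nodes:
                raise ValueError(f"{spec.name}: ontology-categorical needs enum nodes")
            pool: set = set()
            for node in spec.dynamic_enum_nodes:
                pool |= {d for d in graph.descendants(node)
                         if not graph.children(d)}
            if not pool:
                raise ValueError(f"{spec.name}: empty allowed leaf set")
            allowed[spec.name] = sorted(pool)

    for p in range(n_patients):
        pid = f"p{p:04d}"
        fixed: dict[str, str] = {}
        for spec in attributes:
            if spec.name in time_invariant:
                if spec.value_class == "ontology-categorical":
                    tid = allowed[spec.name][rng.integers(len(allowed[spec.name]))]
                    fixed[spec.name] = graph[tid].label
                else:
                    fixed[spec.name] = ["Male", "Female"][rng.integers(2)]
        truth_rows.append({"participant_id": pid, **fixed})
        for s in range(samples_per_patient):
            row = {"study_name": study_name, "participant_id": pid,
                   "sample_id": f"s{s:02d}"}
            for spec in attributes:
                if spec.name in fixed:
                    row[spec.name] = fixed[spec.name]
                elif spec.value_class == "ontology-categorical":
                    k = 1 if spec.kind == "single" else int(rng.integers(1, 4))
                    picks = rng.choice(len(allowed[spec.name]),
                                       size=min(k, len(allowed[spec.name])),
                                       replace=False)
                    labels = [graph[allowed[spec.name][i]].label for i in picks]
                    row[spec.name] = ";".join(labels)
                elif spec.value_class == "numeric-with-unit":
                    row[spec.name] = f"{int(rng.integers(18, 90))} years"
                else:
                    row[spec.name] = _WORDS[rng.integers(len(_WORDS))]
            rows.append(row)

    table = pd.DataFrame(rows)
    table["curation_id"] = add_curation_ids(
        table, ["study_name", "participant_id", "sample_id"])
    return table, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def _slug(value: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", str(value).casefold()).strip("_")


def _make_alias(label: str, variant: int) -> str:
    """Deterministic curator-style aliases: initials+digits or squashed form."""
    words = str(label).split()
    digits = "".join(ch for ch in label if ch.isdigit())
    if variant == 0:
        return "".join(w[0] for w in words) + digits
    return "_".join(w[:4] for w in words)


def _typo(token: str, rng) -> str:
    s = list(str(token))
    if len(s) < 2:
        return str(token) + "x"
    i = int(rng.integers(len(s) - 1))
    if rng.random() < 0.5:
        s[i], s[i + 1] = s[i + 1], s[i]
    else:
        del s[i]
    out = "".join(s)
    return out if out != token else token[:-1]


@dataclass
class CorruptionResult:
    messy: pd.DataFrame
    maps: dict                      # attribute/source column → CurationMap
    log: pd.DataFrame               # one row per injected corruption
    plan_edges: dict                # curated attribute → source columns
    binary_map: dict                # (column, token) → value, for CleaningRules
    config: CorruptionConfig
    unrecoverable: set = field(default_factory=set)  # (curation_id, attribute)


def corrupt_metadata(clean: pd.DataFrame,
                     config: CorruptionConfig,
                     attributes: Sequence[AttributeSpec],
                     graph: Optional[OntologyGraph] = None,
                     time_invariant: Sequence[str] = ("sex", "ancestry"),
                     dispersal_attribute: Optional[str] = None,
                     binary_attribute: Optional[str] = None) -> CorruptionResult:
    """Inject seeded corruptions into a clean cohort.

    Passes, in order: alias substitution → within-patient conflicts (exactly
    one flipped sample per affected patient) → cross-column misplacement →
    typos → binary re-encoding of selected values → dispersal of one
    attribute over sparse part-columns.  The oracle maps cover aliases (and
    identity rows for untouched labels); typos and misplacements are logged
    as unrecoverable instead.
    """
    rng = np.random.default_rng(config.seed)
    messy = clean.copy()
    log: list[dict] = []
    unrecoverable: set = set()
    attr_names = [a.name for a in attributes]
    cat_attrs = [a for a in attributes if a.value_class == "ontology-categorical"]
    plan_edges: dict[str, list] = {a.name: [a.name] for a in attributes}
    binary_map: dict = {}

    # oracle maps: identity rows for every true label, plus alias rows added
    # as aliases are injected
    maps: dict[str, CurationMap] = {}
    entries: dict[str, dict] = {}
    for spec in cat_attrs:
        entries[spec.name] = {}
        for cell in clean[spec.name].dropna():
            for tok in str(cell).split(";"):
                tok = tok.strip()
                if tok and tok.casefold() not in entries[spec.name]:
                    tid = (graph.resolve_label(tok)[0]
                           if graph is not None and graph.resolve_label(tok) else None)
                    entries[spec.name][tok.casefold()] = CurationMapEntry(
                        tok, tok, tid, tid.split(":")[0] if tid else None)

    def add_alias(attr: str, alias: str, truth: str) -> None:
        key = alias.casefold()
        if key not in entries[attr]:
            base = entries[attr][truth.casefold()]
            entries[attr][key] = replace(base, original_value=alias)

    # ---- pass 1: alias substitution (recoverable) ----
    for spec in cat_attrs:
        for idx in messy.index:
            cell = messy.at[idx, spec.name]
            if is_na(cell):
                continue
            toks = str(cell).split(";")
            changed = False
            for j, tok in enumerate(toks):
                if tok and rng.random() < config.abbreviation_rate:
                    alias = _make_alias(tok, int(rng.integers(2)))
                    if alias.casefold() == tok.casefold():
                        continue
                    add_alias(spec.name, alias, tok)
                    log.append({"kind": "alias", "curation_id": messy.at[idx, "curation_id"],
                                "attribute": spec.name, "column": spec.name,
                                "original": tok, "corrupted": alias, "recoverable": True})
                    toks[j] = alias
                    changed = True
            if changed:
                messy.at[idx, spec.name] = ";".join(toks)

    # ---- pass 2: within-patient conflicts on time-invariant attributes ----
    ti_attrs = [a for a in attributes if a.name in time_invariant]
    if ti_attrs and config.conflict_rate > 0:
        for _, group in messy.groupby("participant_id", sort=False):
            if rng.random() >= config.conflict_rate or len(group) < 2:
                continue
            spec = ti_attrs[int(rng.integers(len(ti_attrs)))]
            ridx = group.index[int(rng.integers(len(group)))]
            current = messy.at[ridx, spec.name]
            alternatives = _alternative_values(spec, current, graph, clean)
            if not alternatives:
                continue
            flipped = alternatives[int(rng.integers(len(alternatives)))]
            messy.at[ridx, spec.name] = flipped
            if (spec.value_class == "ontology-categorical"
                    and flipped.casefold() not in entries[spec.name]):
                tid = (graph.resolve_label(flipped)[0]
                       if graph is not None and graph.resolve_label(flipped) else None)
                entries[spec.name][flipped.casefold()] = CurationMapEntry(
                    flipped, flipped, tid, tid.split(":")[0] if tid else None)
            log.append({"kind": "conflict", "curation_id": messy.at[ridx, "curation_id"],
                        "attribute": spec.name, "column": spec.name,
                        "original": current, "corrupted": flipped,
                        "recoverable": len(group) >= 3})
            if len(group) < 3:
                unrecoverable.add((messy.at[ridx, "curation_id"], spec.name))

    # ---- pass 3: misplacement (unrecoverable, both cells) ----
    if config.misplacement_rate > 0 and len(attr_names) >= 2:
        for idx in messy.index:
            if rng.random() >= config.misplacement_rate:
                continue
            a, b = rng.choice(len(attr_names), size=2, replace=False)
            src, dst = attr_names[a], attr_names[b]
            val = messy.at[idx, src]
            if is_na(val):
                continue
            old = messy.at[idx, dst]
            messy.at[idx, dst] = val
            messy.at[idx, src] = None
            cid = messy.at[idx, "curation_id"]
            log.append({"kind": "misplacement", "curation_id": cid,
                        "attribute": src, "column": dst,
                        "original": val, "corrupted": val, "recoverable": False})
            unrecoverable.add((cid, src))
            unrecoverable.add((cid, dst))
            if old is not None and not is_na(old):
                log.append({"kind": "misplacement-overwrite", "curation_id": cid,
                            "attribute": dst, "column": dst,
                            "original": old, "corrupted": val, "recoverable": False})

    # ---- pass 4: typos (unrecoverable; no oracle map entry) ----
    for spec in cat_attrs:
        for idx in messy.index:
            cell = messy.at[idx, spec.name]
            if is_na(cell):
                continue
            toks = str(cell).split(";")
            changed = False
            for j, tok in enumerate(toks):
                if tok and rng.random() < config.typo_rate:
                    bad = _typo(tok, rng)
                    if bad.casefold() in entries[spec.name]:
                        continue  # collided with a real key; skip, keep exactness
                    cid = messy.at[idx, "curation_id"]
                    log.append({"kind": "typo", "curation_id": cid,
                                "attribute": spec.name, "column": spec.name,
                                "original": tok, "corrupted": bad,
                                "recoverable": False})
                    unrecoverable.add((cid, spec.name))
                    toks[j] = bad
                    changed = True
            if changed:
                messy.at[idx, spec.name] = ";".join(toks)

    # ---- pass 5: binary re-encoding (recoverable via binary_map) ----
    if binary_attribute and config.binary_encode_rate > 0:
        spec = next(a for a in attributes if a.name == binary_attribute)
        distinct = sorted({t.strip() for c in clean[spec.name].dropna()
                           for t in str(c).split(";") if t.strip()})
        chosen = [v for v in distinct if rng.random() < config.binary_encode_rate]
        for value in chosen:
            col = _slug(value)
            messy[col] = None
            for idx in messy.index:
                cell = messy.at[idx, spec.name]
                if is_na(cell):
                    continue
                toks = [t.strip() for t in str(cell).split(";") if t.strip()]
                if value in toks:
                    toks.remove(value)
                    messy.at[idx, spec.name] = ";".join(toks) if toks else None
                    messy.at[idx, col] = "yes"
                    log.append({"kind": "binary", "curation_id": messy.at[idx, "curation_id"],
                                "attribute": spec.name, "column": col,
                                "original": value, "corrupted": "yes",
                                "recoverable": True})
            binary_map[(col, "yes")] = value
            plan_edges[spec.name].append(col)
            entries.setdefault(spec.name, {})
            if value.casefold() not in entries[spec.name]:
                entries[spec.name][value.casefold()] = CurationMapEntry(value, value)
            maps_key_entry = entries[spec.name][value.casefold()]
            entries.setdefault(col, {})[value.casefold()] = replace(
                maps_key_entry, original_value=value)

    # ---- pass 6: dispersal over sparse part-columns (recoverable) ----
    if dispersal_attribute and config.dispersal_columns > 1:
        spec = next(a for a in attributes if a.name == dispersal_attribute)
        parts = [f"{spec.name}__part{i+1}" for i in range(config.dispersal_columns)]
        for col in parts:
            messy[col] = None
        for idx in messy.index:
            cell = messy.at[idx, spec.name]
            if is_na(cell):
                continue
            part = parts[int(rng.integers(len(parts)))]
            messy.at[idx, part] = cell
            log.append({"kind": "dispersal", "curation_id": messy.at[idx, "curation_id"],
                        "attribute": spec.name, "column": part,
                        "original": cell, "corrupted": cell, "recoverable": True})
        messy = messy.drop(columns=[spec.name])
        plan_edges[spec.name] = parts + [
            c for c in plan_edges[spec.name] if c != spec.name]
        for col in parts:
            entries.setdefault(col, dict(entries.get(spec.name, {})))

    # An unrecoverable corruption on a time-invariant attribute can perturb
    # the whole patient's consensus vote (e.g. turn a clear plurality into a
    # tie), so the exclusion set extends to every sample of that patient for
    # that attribute.
    ti = set(time_invariant)
    by_cid = clean.set_index("curation_id")["participant_id"]
    extra = set()
    for cid, attr in unrecoverable:
        if attr in ti and cid in by_cid.index:
            pid = by_cid[cid]
            for cid2 in clean.loc[clean["participant_id"] == pid, "curation_id"]:
                extra.add((cid2, attr))
    unrecoverable |= extra

    for attr, emap in entries.items():
        maps[attr] = CurationMap(attr, list(emap.values()))

    log_df = pd.DataFrame(
        log, columns=["kind", "curation_id", "attribute", "column",
                      "original", "corrupted", "recoverable"])
    return CorruptionResult(messy=messy, maps=maps, log=log_df,
                            plan_edges=plan_edges, binary_map=binary_map,
                            config=config, unrecoverable=unrecoverable)


def _alternative_values(spec: AttributeSpec, current,
                        graph: Optional[OntologyGraph],
                        clean: pd.DataFrame) -> list:
    """Legal different values a conflict flip may introduce (sibling leaves)."""
    if spec.value_class == "ontology-categorical" and graph is not None:
        pool: set = set()
        for node in spec.dynamic_enum_nodes:
            pool |= {graph[d].label for d in graph.descendants(node)
                     if not graph.children(d)}
    else:
        pool = {str(v) for v in clean[spec.name].dropna()}
    return sorted(v for v in pool if v != current)


# ---------------------------------------------------------------------------
# recovery harness
# ---------------------------------------------------------------------------

def recover_cohort(result: CorruptionResult,
                   attributes: Sequence[AttributeSpec],
                   graph: Optional[OntologyGraph] = None,
                   time_invariant: Sequence[str] = ("sex", "ancestry")) -> pd.DataFrame:
    """Run the map-driven pipeline over a corrupted cohort.

    Harmonizes every attribute through the oracle curation maps and cleaning
    rules, then applies majority consensus to the time-invariant attributes.
    Returns a table with one plain column per attribute (curated values,
    provenance columns dropped) plus the identifier columns.
    """
    rules = CleaningRules(binary_map=result.binary_map)
    kinds = {a.name: a.kind for a in attributes}
    harmonized, _ = harmonize_table(result.messy, result.plan_edges, result.maps,
                                    rules, graph, kinds)
    out = result.messy[["study_name", "participant_id", "sample_id",
                        "curation_id"]].copy()
    for spec in attributes:
        out[spec.name] = harmonized[f"curated_{spec.name}"]
    for name in time_invariant:
        if name in out.columns:
            _, col = majority_consensus(out, name, "participant_id",
                                        time_invariant=True)
            out[name] = col
    return out


def recovery_report(recovered: pd.DataFrame,
                    clean: pd.DataFrame,
                    result: CorruptionResult,
                    attributes: Sequence[AttributeSpec]) -> dict:
    """Compare recovered cells with ground truth outside the unrecoverable set.

    Multi-valued cells compare as canonical token sets (pooling across part
    columns does not preserve token order).  Returns counts and the fraction
    recovered; ``mismatches`` lists any eligible cell that differs.
    """
    merged = recovered.set_index("curation_id")
    truth = clean.set_index("curation_id")
    total = matched = 0
    mismatches = []
    for spec in attributes:
        multi = spec.kind != "single"
        for cid in truth.index:
            if (cid, spec.name) in result.unrecoverable:
                continue
            t, r = truth.at[cid, spec.name], merged.at[cid, spec.name]
            total += 1
            if is_na(t) and is_na(r):
                matched += 1
                continue
            if is_na(t) != is_na(r):
                mismatches.append((cid, spec.name, t, r))
                continue
            if multi:
                same = (set(str(t).split(";")) ==
                        set(str(r).split(";")))
            else:
                same = canonical_multi(t) == canonical_multi(r)
            if same:
                matched += 1
            else:
                mismatches.append((cid, spec.name, t, r))
    return {"cells": total, "recovered": matched,
            "fraction": matched / total if total else 1.0,
            "mismatches": mismatches}
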