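"""File readers/writers, merge-plan configuration, and the pipeline driver.

A single config file (YAML or JSON) drives a run: reproducible runs are a
file, not a shell history.  The config names the metadata table, data
dictionary, ontology snapshot, per-attribute curation maps, merge-plan edges,
dynamic enums, the consensus whitelist and constraint rules.  Cross-
references are validated at load, fail-fast, with every dangling reference
listed (not just the first).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import etl, metrics, validation
from .consensus import decisions_to_frame, majority_consensus
from .etl import CleaningRules, CurationMap
from .model import (DataDictionary, add_curation_ids, release_columns)
from .ontology import OntologyGraph, read_obo, read_term_table
from .validation import ConstraintRule, DynamicEnum

logger = logging.getLogger("metaharm")

__all__ = ["MergePlan", "LoadedInputs", "ConfigError", "read_table",
           "write_table", "load_inputs", "run_pipeline", "PIPELINE_STAGES"]

PIPELINE_STAGES = ("harmonize", "validate", "consensus", "metrics", "schema")


class ConfigError(ValueError):
    """Aggregated load-time diagnostics: every problem, file by file."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("configuration errors:\n  " + "\n  ".join(self.problems))


# ---------------------------------------------------------------------------
# table IO  (CSV/TSV, UTF-8, header required; NA = empty cell or literal "NA")
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_table(path) -> pd.DataFrame:
    """Read a metadata table; empty cells and the literal ``NA`` parse to NA,
    every other token passes through to cleaning untouched."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return df.replace({"": None, "NA": None})


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table; NA encoded as empty field."""
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep="")


# ---------------------------------------------------------------------------
# merge plan / config
# ---------------------------------------------------------------------------

@dataclass
class MergePlan:
    """Declarative original→curated mapping plus validation resources."""

    edges: dict                       # curated attribute → ordered source columns
    id_fields: list
    enums: dict = field(default_factory=dict)        # attribute → DynamicEnum
    consensus: list = field(default_factory=list)    # time-invariant whitelist
    constraints: list = field(default_factory=list)  # ConstraintRule list
    many_to_many: bool = False

    @property
    def sources(self) -> list:
        seen, out = set(), []
        for cols in self.edges.values():
            for c in cols:
                if c not in seen:
                    seen.add(c)
                    out.append(c)
        return out


@dataclass
class LoadedInputs:
    table: pd.DataFrame
    dictionary: DataDictionary
    plan: MergePlan
    graph: Optional[OntologyGraph]
    maps: dict
    rules: CleaningRules
    config_dir: str = "."


def _resolve(base: str, path: str) -> str:
    return path if os.path.isabs(path) else os.path.join(base, path)


def load_inputs(config_path) -> LoadedInputs:
    """Load and cross-validate everything a pipeline run needs.

    Raises :class:`ConfigError` carrying the exhaustive list of problems
    (missing files, edges naming unknown attributes, enum nodes absent from
    the ontology, unreadable maps).  Logs a load summary on success.
    """
    base = os.path.dirname(os.path.abspath(str(config_path)))
    with open(config_path) as fh:
        cfg = (json.load(fh) if str(config_path).endswith(".json")
               else yaml.safe_load(fh)) or {}
    problems: list[str] = []

    def load_file(key, reader, required=True):
        rel = cfg.get(key)
        if not rel:
            if required:
                problems.append(f"config: missing required key {key!r}")
            return None
        path = _resolve(base, rel)
        if not os.path.exists(path):
            problems.append(f"{key}: file not found: {path}")
            return None
        try:
            return reader(path)
        except Exception as exc:  # aggregate parse failures with location
            problems.append(f"{key} ({path}): {exc}")
            return None

    table = load_file("metadata", read_table)
    dictionary = load_file("dictionary", DataDictionary.from_csv)
    graph = None
    if cfg.get("ontology"):
        reader = (read_obo if str(cfg["ontology"]).endswith(".obo")
                  else read_term_table)
        graph = load_file("ontology", reader, required=False)

    edges = {k: list(v) for k, v in (cfg.get("edges") or {}).items()}
    id_fields = list(cfg.get("id_fields") or [])
    if not id_fields:
        problems.append("config: missing required key 'id_fields'")

    maps: dict[str, CurationMap] = {}
    maps_dir = cfg.get("maps_dir")
    if maps_dir:
        mdir = _resolve(base, maps_dir)
        if not os.path.isdir(mdir):
            problems.append(f"maps_dir: directory not found: {mdir}")
        else:
            for fn in sorted(os.listdir(mdir)):
                if fn.endswith(".csv"):
                    try:
                        cmap = CurationMap.from_csv(os.path.join(mdir, fn))
                        maps[cmap.attribute] = cmap
                    except Exception as exc:
                        problems.append(f"curation map {fn}: {exc}")

    rules = CleaningRules()
    if cfg.get("cleaning"):
        try:
            rules = CleaningRules.from_config(_resolve(base, cfg["cleaning"]))
        except Exception as exc:
            problems.append(f"cleaning ({cfg['cleaning']}): {exc}")

    enums: dict[str, DynamicEnum] = {}
    for attr, spec in (cfg.get("enums") or {}).items():
        try:
            enums[attr] = DynamicEnum(
                attribute=attr, enum_nodes=list(spec.get("nodes", [])),
                include_self=bool(spec.get("include_self", False)),
                allow_combinations=bool(spec.get("allow_combinations", True)))
        except Exception as exc:
            problems.append(f"enum {attr}: {exc}")

    constraints: list[ConstraintRule] = []
    for rule in (cfg.get("constraints") or []):
        try:
            constraints.append(ConstraintRule(
                id=rule["id"], if_attribute=rule["if_attribute"],
                if_values=set(rule["if_values"]),
                then_attribute=rule["then_attribute"],
                forbidden_values=set(rule["forbidden_values"])))
        except Exception as exc:
            problems.append(f"constraint {rule.get('id', '?')}: {exc}")

    # cross-reference validation — exhaustive, not first-only
    if dictionary is not None:
        for curated in edges:
            if curated not in dictionary:
                problems.append(f"edges: curated attribute {curated!r} "
                                "not in the data dictionary")
    if table is not None:
        for curated, cols in edges.items():
            for c in cols:
                if c not in table.columns:
                    problems.append(f"edges[{curated}]: source column {c!r} "
                                    "absent from the metadata table")
        for f in id_fields:
            if f not in table.columns:
                problems.append(f"id_fields: column {f!r} absent from the metadata table")
    if graph is not None:
        for attr, enum in enums.items():
            for node in enum.enum_nodes:
                if node not in graph:
                    problems.append(f"enum {attr}: node {node!r} not in the ontology")
    for attr in maps:
        if edges and attr not in {s for cols in edges.values() for s in cols} \
                and (dictionary is None or attr not in dictionary):
            problems.append(f"curation map {attr!r} references an unknown attribute")

    if problems:
        raise ConfigError(problems)

    plan = MergePlan(edges=edges, id_fields=id_fields, enums=enums,
                     consensus=list(cfg.get("consensus") or []),
                     constraints=constraints,
                     many_to_many=bool(cfg.get("many_to_many", False)))
    logger.info("loaded %d rows x %d columns, %d dictionary attributes, "
                "%d ontology terms, %d curation maps (%d entries)",
                len(table), len(table.columns), len(dictionary),
                len(graph) if graph else 0, len(maps),
                sum(len(m) for m in maps.values()))
    return LoadedInputs(table=table, dictionary=dictionary, plan=plan,
                        graph=graph, maps=maps, rules=rules, config_dir=base)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(inputs: LoadedInputs,
                 out_dir: str,
                 stages: Sequence[str] = PIPELINE_STAGES,
                 timestamp: Optional[str] = None) -> dict:
    """Run the requested stages and write their artifacts under *out_dir*.

    Stages: harmonize (provenance + release tables), validate (enum +
    constraint report), consensus (decision log), metrics (per-attribute
    quality metrics), schema (merging schema).  All downstream stages require
    harmonize.  *timestamp* stamps the ``last_modified`` column; pass a fixed
    date for byte-identical reruns.  Returns a manifest of per-stage counts.
    """
    stages = list(stages)
    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stages: {unknown}")
    downstream = [s for s in stages if s != "harmonize"]
    if downstream and "harmonize" not in stages:
        raise ValueError(f"stages {downstream} require the harmonize stage")
    os.makedirs(out_dir, exist_ok=True)

    table, plan, dic = inputs.table, inputs.plan, inputs.dictionary
    manifest: dict = {"stages": stages, "rows": len(table)}
    kinds = {name: dic[name].kind for name in plan.edges if name in dic}

    harmonized, conflicts = etl.harmonize_table(
        table, plan.edges, inputs.maps, inputs.rules, inputs.graph, kinds)
    harmonized.insert(0, "curation_id", add_curation_ids(table, plan.id_fields).values)
    if timestamp is None:
        timestamp = pd.Timestamp.today().strftime("%Y-%m-%d")
    harmonized["last_modified"] = timestamp
    manifest["harmonize"] = {"attributes": len(plan.edges),
                             "conflicts": len(conflicts)}

    decisions = []
    if "consensus" in stages and plan.consensus:
        patient_col = plan.id_fields[1] if len(plan.id_fields) > 1 else plan.id_fields[0]
        work = harmonized.copy()
        work[patient_col] = table[patient_col].values
        for attr in plan.consensus:
            col = f"curated_{attr}"
            if col not in work.columns:
                continue
            dec, newcol = majority_consensus(work, col, patient_col,
                                             time_invariant=True)
            harmonized[col] = newcol.values
            for d in dec:
                d.attribute = attr
            decisions.extend(dec)
        manifest["consensus"] = {
            "decisions": len(decisions),
            "inferred": sum(len(d.inferred_rows) for d in decisions),
            "corrected": sum(len(d.corrected_rows) for d in decisions),
            "tied_na": sum(d.action == "tied-NA" for d in decisions)}
    if "consensus" in stages:
        decisions_to_frame(decisions).to_csv(
            os.path.join(out_dir, "consensus_log.tsv"), sep="\t", index=False)

    write_table(harmonized, os.path.join(out_dir, "harmonized_provenance.csv"))
    write_table(harmonized[release_columns(harmonized.columns)],
                os.path.join(out_dir, "harmonized_release.csv"))

    if "validate" in stages:
        report = validation.ValidationReport()
        if inputs.graph is not None:
            for attr, enum in plan.enums.items():
                col = f"curated_{attr}"
                if col not in harmonized.columns:
                    continue
                rep = validation.validate_dynamic_enum(
                    harmonized[col].tolist(), enum, inputs.graph,
                    ids=harmonized.get(f"{col}_ontology_term_id"),
                    curation_ids=harmonized["curation_id"].tolist())
                report.extend(rep)
        if plan.constraints:
            rules_ok = [r for r in plan.constraints
                        if f"curated_{r.if_attribute}" in harmonized.columns
                        and f"curated_{r.then_attribute}" in harmonized.columns]
            renamed = [ConstraintRule(r.id, f"curated_{r.if_attribute}",
                                      r.if_values, f"curated_{r.then_attribute}",
                                      r.forbidden_values) for r in rules_ok]
            report.extend(validation.check_constraints(harmonized, renamed))
        report.write_tsv(os.path.join(out_dir, "validation_report.tsv"))
        manifest["validate"] = {"violations": len(report)}

    if "metrics" in stages:
        rows = []
        for attr, sources in plan.edges.items():
            col = f"curated_{attr}"
            comp, uniq = metrics.attribute_metrics(harmonized[col])
            rate = metrics.correction_rate(
                table[sources[0]], harmonized[col],
                many_to_many=plan.many_to_many or len(sources) > 1,
                rules=inputs.rules, attribute=sources[0])
            rows.append({"attribute": attr, "completeness": comp,
                         "unique_values": uniq, "compression": len(sources),
                         "correction_rate": rate if rate is not None else ""})
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
        manifest["metrics"] = {"attributes": len(rows)}

    if "schema" in stages:
        schema = metrics.build_merging_schema(plan.edges, table, harmonized)
        schema.to_csv(os.path.join(out_dir, "merging_schema.csv"), index=False)
        manifest["schema"] = {"edges": len(schema)}

    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
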