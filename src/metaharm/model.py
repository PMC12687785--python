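"""Attribute and table data model for harmonized clinical metadata.

Sample-level metadata is modelled as a flat table (rows = samples, columns =
attributes, cells = strings or NA).  Curated attributes carry a provenance
naming schema (``curated_*``, ``original_*_value``, ``curated_*_source``) plus
a per-sample ``curation_id`` built by joining the study/participant/sample
identifier columns with ``:``.

Attributes come in three structural kinds:

``single``
    one value per cell;
``multi``
    several delimited standardized values per cell (default delimiter ``;``);
``composite``
    several named features under one generic attribute, encoded as
    ``name:value`` pairs joined by the delimiter (e.g. a biomarker panel).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "AttributeSpec",
    "DataDictionary",
    "StructureReport",
    "build_curation_id",
    "add_curation_ids",
    "provenance_names",
    "release_columns",
    "validate_structure",
    "render_dictionary",
    "is_na",
]

KINDS = ("single", "multi", "composite")
VALUE_CLASSES = ("ontology-categorical", "numeric-with-unit", "free-text", "identifier")

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*$")


def is_na(x) -> bool:
    """True for None / NaN / pd.NA; never raises on strings."""
    return x is None or (isinstance(x, float) and x != x) or x is pd.NA


@dataclass
class AttributeSpec:
    """Declarative description of one curated attribute.

    Parameters
    ----------
    name
        Attribute identifier (column name without prefixes).
    kind
        ``single``, ``multi`` or ``composite``.
    value_class
        ``ontology-categorical``, ``numeric-with-unit``, ``free-text`` or
        ``identifier``.
    delimiter
        Token delimiter for multi/composite cells.
    dynamic_enum_nodes
        CURIEs of ontology terms whose descendants constitute the allowed
        values (empty for non-enumerated attributes).
    details_partner
        Name of a paired ``*_details`` attribute preserving finer-grained
        terms, if any.
    unit_attribute
        Name of the companion unit column for numeric-with-unit attributes.
    members
        Named features of a composite attribute (used by the data-dictionary
        curation rendering).
    """

    name: str
    kind: str = "single"
    value_class: str = "free-text"
    delimiter: str = ";"
    dynamic_enum_nodes: list = field(default_factory=list)
    details_partner: Optional[str] = None
    unit_attribute: Optional[str] = None
    required: bool = False
    members: list = field(default_factory=list)

    def __post_init__(self):
        if not _IDENT_RE.match(self.name):
            raise ValueError(f"invalid attribute name: {self.name!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown attribute kind: {self.kind!r}")
        if self.value_class not in VALUE_CLASSES:
            raise ValueError(f"unknown value class: {self.value_class!r}")
        if self.kind in ("multi", "composite") and not self.delimiter:
            raise ValueError(f"{self.name}: kind={self.kind} requires a delimiter")
        if self.delimiter and len(self.delimiter) != 1:
            raise ValueError(f"{self.name}: delimiter must be a single character")
        if self.value_class == "numeric-with-unit" and not self.unit_attribute:
            raise ValueError(f"{self.name}: numeric-with-unit requires unit_attribute")


class DataDictionary:
    """Ordered collection of :class:`AttributeSpec` with cross-reference checks."""

    def __init__(self, attributes: Iterable[AttributeSpec], version: str = "0"):
        self.version = version
        self._attrs: dict[str, AttributeSpec] = {}
        for spec in attributes:
            if spec.name in self._attrs:
                raise ValueError(f"duplicate attribute name: {spec.name}")
            self._attrs[spec.name] = spec
        for spec in self._attrs.values():
            for ref, what in ((spec.details_partner, "details_partner"),
                              (spec.unit_attribute, "unit_attribute")):
                if ref is not None and ref not in self._attrs:
                    raise ValueError(
                        f"{spec.name}: {what} {ref!r} does not resolve in the dictionary"
                    )

    def __iter__(self) -> Iterator[AttributeSpec]:
        return iter(self._attrs.values())

    def __len__(self) -> int:
        return len(self._attrs)

    def __contains__(self, name: str) -> bool:
        return name in self._attrs

    def __getitem__(self, name: str) -> AttributeSpec:
        return self._attrs[name]

    @property
    def names(self) -> list[str]:
        return list(self._attrs)

    # ---- CSV round trip -------------------------------------------------

    _COLUMNS = ["name", "kind", "value_class", "delimiter", "dynamic_enum_nodes",
                "details_partner", "unit_attribute", "required", "members"]

    @classmethod
    def from_csv(cls, path, version: str = "0") -> "DataDictionary":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        attrs = []
        for _, row in df.iterrows():
            attrs.append(AttributeSpec(
                name=row["name"],
                kind=row.get("kind") or "single",
                value_class=row.get("value_class") or "free-text",
                delimiter=row.get("delimiter") or ";",
                dynamic_enum_nodes=[t for t in (row.get("dynamic_enum_nodes") or "").split("|") if t],
                details_partner=row.get("details_partner") or None,
                unit_attribute=row.get("unit_attribute") or None,
                required=str(row.get("required", "")).strip().lower() in ("true", "1", "yes"),
                members=[t for t in (row.get("members") or "").split("|") if t],
            ))
        return cls(attrs, version=version)

    def to_csv(self, path) -> None:
        rows = []
        for a in self:
            rows.append({
                "name": a.name, "kind": a.kind, "value_class": a.value_class,
                "delimiter": a.delimiter,
                "dynamic_enum_nodes": "|".join(a.dynamic_enum_nodes),
                "details_partner": a.details_partner or "",
                "unit_attribute": a.unit_attribute or "",
                "required": str(a.required).lower(),
                "members": "|".join(a.members),
            })
        pd.DataFrame(rows, columns=self._COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# curation_id and provenance naming
# ---------------------------------------------------------------------------

def build_curation_id(components: Sequence) -> str:
    """Join sample identifier components with ``:`` into a curation_id.

    Follows the ``study_name:participant_id[:sample_id]`` convention.  Missing
    or empty components and components containing the ``:`` delimiter are
    hard errors rather than silent corruption.
    """
    parts = []
    for c in components:
        if is_na(c) or str(c).strip() == "":
            raise ValueError("missing identifier component for curation_id")
        s = str(c).strip()
        if ":" in s:
            raise ValueError(f"delimiter collision: identifier component {s!r} contains ':'")
        parts.append(s)
    if not parts:
        raise ValueError("missing identifier component for curation_id")
    return ":".join(parts)


def add_curation_ids(table: pd.DataFrame, id_fields: Sequence[str]) -> pd.Series:
    """Compute the curation_id for every row of *table* (not added in place)."""
    missing = [f for f in id_fields if f not in table.columns]
    if missing:
        raise KeyError(f"id fields absent from table: {missing}")
    return table.apply(lambda r: build_curation_id([r[f] for f in id_fields]), axis=1)


def provenance_names(attribute: str, option: Optional[str] = None) -> set[str]:
    """Full provenance column set for one curated attribute.

    Always ``curated_X``, ``curated_X_ontology_term_id``, ``curated_X_source``
    and ``original_X_value``; ``curated_X_{option}`` (e.g. ``curated_age_unit``)
    is added when *option* is given.
    """
    if not _IDENT_RE.match(attribute):
        raise ValueError(f"invalid attribute name: {attribute!r}")
    names = {
        f"curated_{attribute}",
        f"curated_{attribute}_ontology_term_id",
        f"curated_{attribute}_source",
        f"original_{attribute}_value",
    }
    if option:
        names.add(f"curated_{attribute}_{option}")
    return names


def release_columns(columns: Iterable[str]) -> list[str]:
    """Columns kept in the release rendering: no original_* / *_source."""
    return [c for c in columns
            if not c.startswith("original_") and not c.endswith("_source")]


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

@dataclass
class StructureReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def add(self, kind: str, column: str, detail: str) -> None:
        self.violations.append({"kind": kind, "column": column, "detail": detail})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.violations, columns=["kind", "column", "detail"])


def _known_columns(dictionary: DataDictionary, id_fields: Sequence[str]) -> set[str]:
    known = set(id_fields) | {"curation_id", "last_modified"}
    for spec in dictionary:
        known.add(spec.name)
        known |= provenance_names(spec.name)
        if spec.unit_attribute:
            known.add(f"curated_{spec.name}_{spec.unit_attribute}")
        if spec.kind == "composite":
            for m in spec.members:
                known.add(f"curated_{spec.name}_{m}")
    return known


def validate_structure(table: pd.DataFrame,
                       dictionary: DataDictionary,
                       id_fields: Sequence[str] = (),
                       provenance: bool = False,
                       allow_duplicate_curation_id: bool = False) -> StructureReport:
    """Check a (possibly harmonized) table against the data dictionary.

    Reports unknown columns, missing required attributes, delimiter characters
    inside single-valued cells, missing provenance partner columns and
    duplicated curation_ids.  ``allow_duplicate_curation_id`` relaxes the
    uniqueness invariant for tables in spread (long) form.
    """
    report = StructureReport()
    known = _known_columns(dictionary, id_fields)

    for col in table.columns:
        if col not in known:
            report.add("unknown-column", col, "column not described by the dictionary")

    for spec in dictionary:
        if spec.required and spec.name not in table.columns \
                and f"curated_{spec.name}" not in table.columns:
            report.add("missing-required", spec.name, "required attribute absent")

    for spec in dictionary:
        if spec.kind != "single":
            continue
        for col in (spec.name, f"curated_{spec.name}"):
            if col not in table.columns:
                continue
            bad = table[col].dropna().astype(str).str.contains(spec.delimiter, regex=False)
            for idx in table.index[table[col].notna()][bad.values]:
                report.add("delimiter-in-single", col,
                           f"row {idx}: single-valued cell contains {spec.delimiter!r}")

    if provenance:
        for spec in dictionary:
            cur, orig = f"curated_{spec.name}", f"original_{spec.name}_value"
            if cur in table.columns and orig not in table.columns:
                report.add("missing-provenance-partner", cur, f"{orig} column absent")

    if "curation_id" in table.columns and not allow_duplicate_curation_id:
        dup = table["curation_id"][table["curation_id"].duplicated(keep=False)]
        for val in sorted(set(dup.dropna())):
            report.add("duplicate-curation-id", "curation_id", f"curation_id {val!r} repeated")

    return report


def render_dictionary(dictionary: DataDictionary, mode: str = "release") -> pd.DataFrame:
    """Render the data dictionary as a flat table.

    ``curation`` mode splits composite attributes into one row per member to
    facilitate detailed editing; ``release`` mode presents each composite
    attribute as a single grouped row.
    """
    if mode not in ("curation", "release"):
        raise ValueError(f"unknown dictionary rendering mode: {mode!r}")
    rows = []
    for spec in dictionary:
        base = {
            "attribute": spec.name, "kind": spec.kind, "value_class": spec.value_class,
            "delimiter": spec.delimiter,
            "dynamic_enum_nodes": "|".join(spec.dynamic_enum_nodes),
            "details_partner": spec.details_partner or "",
            "unit_attribute": spec.unit_attribute or "",
            "required": spec.required,
        }
        if mode == "curation" and spec.kind == "composite" and spec.members:
            for m in spec.members:
                rows.append({**base, "member": m})
        else:
            rows.append({**base, "member": "|".join(spec.members)})
    cols = ["attribute", "member", "kind", "value_class", "delimiter",
            "dynamic_enum_nodes", "details_partner", "unit_attribute", "required"]
    return pd.DataFrame(rows, columns=cols)
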