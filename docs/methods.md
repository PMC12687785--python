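# Methods and design notes

## The harmonization model

`metaharm` treats sample-level metadata as a flat table of string cells and
harmonization as a deterministic, auditable transform over it:

1. **Clean** each cell: trim; map NA-lexicon tokens (default `"", na, n/a,
   not available, not provided, -`) and empty strings to NA; normalize
   delimiter aliases (`,`, `|`) to `;`; re-express attribute-scoped binary
   encodings (`antibiotics=yes` → `Antibiotic`) and curator abbreviations.
2. **Map** each token through the attribute's curation map — an explicit
   `original value → (ontology term, CURIE, source db)` dictionary.  Keys
   are normalized by trim + casefold *only*; there is no fuzzy matching in
   the transform path, so the same inputs always produce the same outputs.
   Fuzzy candidate suggestion exists solely in the curator work-queue
   (`unmapped_report(..., suggest=True)`).
3. **Pool** the mapped tokens from all source columns of a curated
   attribute, de-duplicate keeping first occurrence (this is what collapses
   several brand names of one generic drug into a single token), and — when
   ontology ids are available — drop terms that are strict ancestors of
   other terms in the cell, consolidating mixed-resolution annotations to
   the most specific information.
4. **Record provenance**: `curated_X`, `curated_X_ontology_term_id`,
   `curated_X_source` (the contributing source columns, in plan order),
   `original_X_value` (the contributing raw cells), a `curation_id` built by
   `:`-joining the identifier columns, and a `last_modified` date
   (ISO-8601, per row; a run may stamp a single shared value).  The release
   rendering drops `original_*` and `*_source` columns; a flag selects it.

Identifier components may not contain `:`; that is an error, not silent
corruption, because `curation_id` must stay splittable.

## Validation

*Dynamic enums.* An attribute's allowed values are the descendant closure of
one or more ontology nodes.  The enum node itself is excluded by default
(only its descendants are values; `include_self` overrides per enum).
Validation prefers CURIEs from the paired `*_ontology_term_id` column —
ids are version-stable — and falls back to case-folded label/synonym lookup.
Multi-token cells pass only if every token passes and the enum permits
combinations.  `*_details` attributes are validated against their own,
wider, enum nodes.

*Round-trip validation.* Each curated (term, id) pair is resolved back
through the ontology snapshot and compared case-insensitively against the
stored label and synonyms; failures are classified `unknown-id`,
`label-mismatch` or `obsolete`.  This runs against a local snapshot, not a
live lookup service, so snapshot/version drift is a known, accepted
limitation.

*Systematic vs random errors.* Discordance records are tallied per study;
any study holding ≥ 50% of all discordances (threshold configurable) is
flagged as a candidate systematic error, to be fixed at the source rather
than record by record.

## Conflict resolution

Majority consensus applies only to attributes whitelisted as time-invariant
(default `sex`, `ancestry`); it refuses anything else, because overwriting
dynamic clinical variables (disease stage, treatment status) would destroy
longitudinal signal.  NA votes are excluded — otherwise missingness could
force ties, and an NA row receiving the winner is precisely the "inferred"
case.  "Majority" is implemented as *unique plurality* (strict top count):
with votes `{M:2, F:1}` all rows become `M`; with a tie all rows become NA.
Patients are grouped by participant id within a study.

A `ConsensusDecision` records per-patient votes, the chosen value, and the
row-level fates (inferred / corrected).  Since one patient can have both
inferred and corrected rows, the single summary action uses the precedence
`tied-NA > corrected > inferred > kept`; the row lists carry the detail.

Granularity conflicts are a separate mechanism: ancestor/descendant chains
collapse to the descendant; incomparable siblings in a single-valued
attribute are irreconcilable and yield NA plus a conflict flag routed to the
validation report — never a silent choice.

## Quality metrics

- completeness = non-NA cells / cells;
- unique values counted per whole cell by default (the merging-schema
  convention); token mode (split on `;` first) is exposed because either
  convention is defensible for multi-valued attributes — callers choose;
- compression = distinct original columns feeding a curated attribute;
- correction rate = fraction of rows (original non-NA) whose curated cell
  differs from the *cleaned* original cell, so whitespace/NA normalization
  does not count as an update, only semantic replacement does.  Under a
  many-to-many plan no row-wise pairing exists and the rate is NA.

## Query and reshape semantics

`tree_filter` expands each query term to itself, its synonyms, and every
descendant's label/synonyms/CURIE (case-folded), then keeps rows whose
tokens intersect the expansion (`any`) or hit every term's expansion
(`all`).  The expansion always contains the literal seed, so hierarchy-aware
filtering is a superset of exact matching, and adding terms under `any` is
monotone.

Composite cells use the dialect `name:value` pairs joined by `;` — declared
as this package's encoding.  `spread_meta` explodes multi cells to one row
per token (deliberately repeating `curation_id`; structural validation
relaxes the uniqueness check for spread tables) and pivots composite cells
to `{attribute}_{name}` columns.  `gather_meta` inverts both up to canonical
form: token order = first appearance, duplicates removed; composite pair
order = spread column order (global first appearance of feature names).
Rows that disagree on context columns make a gather non-rectangular and
raise.  A literal `;` inside a value is unsupported (load-time error for
curation maps); no escaping rule is defined in this version.

## Synthetic cohorts: what they emulate, and what not

The generator builds rooted ontology DAGs (deterministic ids, seeded
synonyms and second parents, edges only toward earlier levels so acyclicity
is structural) and cohorts of `n_patients × samples_per_patient` rows whose
ontology-categorical values are uniform draws from enum-node leaves and
whose time-invariant attributes are constant within patient.

Corruption passes mirror recurring legacy-metadata pathologies, at default
rates chosen to represent a plausibly messy cohort: alias/abbreviation
substitution 30% of tokens (the dominant real-world problem), typos 2% of
tokens, misplaced values 2% of rows, one conflicting sample in 20% of
patients (exactly one flip per affected patient, so plurality survives at
≥ 3 samples), binary re-encoding of 15% of one attribute's values, and
dispersal of one attribute over 3 sparse part-columns.

The generator emits the oracle curation maps needed to undo the recoverable
corruptions.  Typos and misplacements are deliberately *excluded* from the
maps — they stand in for errors only manual review fixes — and are logged as
unrecoverable instead.  When an unrecoverable corruption touches a
time-invariant attribute, the exclusion set extends to the whole patient for
that attribute, because a lost or garbled vote can legitimately perturb the
consensus outcome (e.g. turn a clear plurality into a tie).  The end-to-end
guarantee tested is: harmonize + consensus over the corrupted table equals
the clean table on **every cell outside that logged exclusion set** —
measuring the map-driven pipeline, not magic recovery of typos.

What the synthetic data does **not** emulate: the empirical value
distributions, attribute counts and missingness structure of real
repositories; ontology-scale graphs (thousands of terms); free-text notes;
or correlated corruption (a sloppy study being sloppy everywhere).  Passing
tests therefore demonstrate correctness of the mechanisms, not expected
recovery rates on any real repository.

## Numerical and parsing choices

- Numeric/unit split: leading numeric literal (integer, decimal, scientific)
  parsed as the value, trimmed remainder as the unit; pure numbers get unit
  NA.  Unparseable cells yield (NA, NA) with a flag, never an exception;
  censored/binned tokens (`>89`, `<5`, `40-49`) are handled by the optional
  range split into explicit min/max.
- NA on disk: empty field or literal `NA` both parse to NA; NA writes as an
  empty field.  "Unknown" is *not* in the default NA lexicon — it is a
  legitimate curated value (e.g. vital status) — and the lexicon is
  configuration.
- Label resolution ranks exact label matches before synonym matches; ties
  across ontology prefixes follow a caller-supplied prefix order (default:
  load order).
- Ontology graphs may contain several prefixes as disjoint components;
  cross-ontology edges are never inferred; cycles are a load error.
- Obsolete terms are excluded from traversal results by default but are
  still traversed *through*, so deprecating an internal node does not hide
  its subtree.

## Problem sizes

The test suite and the acceptance script run at desk scale: 100 random DAGs
of ≤ 50 nodes for oracle-equivalence checks, 200 random tables for reshaping
round trips, 100 injected corruptions for round-trip validation, 100–120
patients × 3 samples (~1,000 attribute cells) for consensus and end-to-end
recovery.  These sizes exercise every code path and keep the whole suite in
seconds; the algorithms themselves are linear in cells and edges and run
unchanged on larger tables.

## Known limitations

- No OWL reasoning and no relationship types beyond `is_a`.
- No automatic ontology-term inference; curation maps are inputs authored by
  curators.
- Offline by design: no live ontology-lookup or repository clients;
  snapshot drift between ontology versions is acknowledged, not resolved.
- Flat tables only; no relational backend.
- No probabilistic or source-weighted voting in consensus.
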