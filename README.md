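# metaharm

Retrospective harmonization of sample-level clinical metadata from omics
repositories.

Legacy metadata in public repositories — metagenomics cohorts, cancer
genomics portals — is plagued by free-text heterogeneity: the same drug
recorded as three brand names, sex encoded as `M`/`male`/`1` across studies,
one concept scattered over a dozen sparse columns, binary `yes`/`no` columns
standing in for categorical values, and outright conflicts between a
patient's samples.  `metaharm` is a toolkit for curators and data engineers
who need to turn such tables into ontology-mapped, provenance-tracked,
queryable metadata **after the fact**, without touching the original data
collection.

## What it does

- **ETL curation engine** — cleans cell values (NA lexicon, delimiter
  aliases, binary encodings, abbreviations), splits numeric/unit cells, and
  applies per-attribute *curation maps* (`original_value →
  curated_ontology_term, curated_ontology_term_id, curated_ontology_term_db`)
  to pool scattered source columns into curated attributes with full
  provenance (`curated_X`, `curated_X_source`, `original_X_value`, a
  `:`-joined `curation_id` per sample).
- **Ontology layer** — an offline is_a DAG (OBO or flat CSV) with descendant/
  ancestor traversal, label+synonym resolution, most-specific-term
  consolidation and shared-ancestor discovery.
- **Validation** — *dynamic enums*: an ontology node whose descendants are
  the allowed values of an attribute (e.g. the eight ancestry categories
  under `HANCESTRO:0004`); round-trip validation of curated term/ID pairs;
  cross-attribute logical constraints (prostate carcinoma ∧ female sex);
  triage of discordances into systematic vs random errors by study share.
- **Conflict resolution** — majority-rule consensus for time-invariant
  attributes (sex, ancestry): unique plurality overwrites, ties become NA,
  NA rows are inferred; granularity conflicts collapse to the most specific
  ontology term.
- **Quality metrics** — compression (originals per curated attribute),
  consolidation (unique values), correction rate (fraction of values updated;
  NA under many-to-many plans) and completeness (non-NA fraction), plus the
  six-column merging schema relating original and curated fields.
- **Query & reshape** — `tree_filter` hierarchy-aware search (a query term
  matches its synonyms and all ontology descendants) and `spread`/`gather`
  reshaping of multi-valued (`a;b;c`) and composite (`name:value;...`)
  attributes.
- **Synthetic cohorts** — a generator of messy cohorts with known ground
  truth (typos, aliases, binary re-encoding, dispersal, misplacement,
  conflicts) used to test the whole pipeline end to end.

## Worked example

The packaged demo project harmonizes a five-sample table whose `treatment`
column mixes generic and brand drug names:

```sh
metaharm harmonize --config src/metaharm/data/demo/config.yaml \
    --out-dir demo_out --timestamp 2026-01-01
```

or from Python:

```python
from metaharm.io import load_inputs, run_pipeline, read_table
from metaharm.data import demo_config_path

inputs = load_inputs(demo_config_path())
run_pipeline(inputs, "demo_out", timestamp="2026-01-01")
print(read_table("demo_out/harmonized_release.csv"))
```

The release rendering comes back as:

```
       curation_id                                     curated_treatment          curated_disease curated_sex
ZellerG_2014:p1:s1 Metformin;Sitagliptin;Insulin Glargine;Insulin Aspart type 2 diabetes mellitus        Male
ZellerG_2014:p1:s2                                             Metformin type 2 diabetes mellitus        Male
ZellerG_2014:p2:s1                                               Aspirin     colorectal carcinoma      Female
    LiJ_2017:p3:s1                                                  None     colorectal carcinoma        Male
    LiJ_2017:p4:s1                                                  None       prostate carcinoma      Female
```

Note the first row: the original cell
`metformin;sitagliptin;lantus;solostar;novorapid` held two brand names of the
same generic insulin (`lantus`, `solostar`), which the curation map collapses
into a single `Insulin Glargine` token.  `curated_sex` is consensus-resolved
per patient (`male` and `m` both map to `Male`).  The validation report flags
one logical impossibility:

```
curation_id      attribute    token   kind        detail
LiJ_2017:p4:s1   curated_sex  female  constraint  rule prostate-female: ...
```

and `metrics.csv` records per-attribute completeness, unique-value counts,
compression and correction rate (here `treatment` has completeness 0.6 —
three of five samples annotated — and correction rate 1.0, every original
value replaced by an ontology term).

Hierarchy-aware querying then finds both treated samples from a single
class-level query, although neither cell contains the query string:

```sh
metaharm query --table demo_out/harmonized_provenance.csv \
    --attribute curated_treatment --terms "antidiabetic agent" \
    --ontology src/metaharm/data/demo/ontology.obo --out hits.csv
# -> 2 of 5 rows matched
```

## Layout

```
src/metaharm/
  model.py       attribute/table data model, provenance naming, structure checks
  ontology.py    ontology DAG, traversal, resolution, round-trip validation
  etl.py         cleaning rules, curation maps, per-attribute harmonization
  validation.py  dynamic enums, constraints, systematic-error triage
  consensus.py   majority rule, granularity reconciliation
  metrics.py     quality metrics, merging schema
  query.py       tree_filter, spread/gather reshaping
  simulate.py    synthetic ontologies and messy cohorts with ground truth
  io.py          config loading, pipeline driver, table IO
  cli.py         `metaharm` command-line interface
  data/          synthetic ancestry snapshot + demo project
```

See `docs/methods.md` for the methods and design notes.
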