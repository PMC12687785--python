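import pandas as pd
import pytest

from metaharm.etl import (CleaningRules, CurationMap, CurationMapEntry,
                          apply_curation_map, clean_value, harmonize_attribute,
                          split_numeric_range, split_numeric_unit,
                          unmapped_report)


class TestCleanValue:
    @pytest.mark.parametrize("raw", ["", "  ", "NA", "n/a", "not provided", "-", None])
    def test_na_tokens_become_na(self, raw):
        assert clean_value(raw, "any", CleaningRules()) is None

    def test_whitespace_trim(self):
        assert clean_value("  male ", "sex", CleaningRules()) == "male"

    def test_binary_map_is_attribute_scoped(self):
        rules = CleaningRules(binary_map={("antibiotics", "yes"): "Antibiotic"})
        assert clean_value("yes", "antibiotics", rules) == "Antibiotic"
        assert clean_value("yes", "smoker", rules) == "yes"

    def test_abbreviation_lexicon_applied_per_token(self):
        rules = CleaningRules(abbreviation_lexicon={"asa": "Aspirin"})
        assert clean_value("ASA;other", "treatment", rules) == "Aspirin;other"

    def test_delimiter_aliases_normalized(self):
        assert clean_value("a, b | c", "x", CleaningRules()) == "a;b;c"

    def test_config_round_trip(self, tmp_path):
        cfg = tmp_path / "rules.yaml"
        cfg.write_text("na_lexicon: ['', unknown]\n"
                       "binary_map:\n  antibiotics:\n    'yes': Antibiotic\n"
                       "abbreviation_lexicon:\n  asa: Aspirin\n")
        rules = CleaningRules.from_config(cfg)
        assert clean_value("Unknown", "x", rules) is None
        assert clean_value("yes", "antibiotics", rules) == "Antibiotic"


class TestSplitNumericUnit:
    @pytest.mark.parametrize("raw, value, unit", [
        ("34 years", 34.0, "years"),
        ("5", 5.0, None),
        ("2.5e3 copies/ml", 2500.0, "copies/ml"),
        ("-1.5 C", -1.5, "C"),
    ])
    def test_parses_leading_numeric(self, raw, value, unit):
        got = split_numeric_unit(raw)
        assert (got.value, got.unit, got.flagged) == (value, unit, False)

    def test_unparseable_is_flagged_not_raised(self):
        got = split_numeric_unit("adult")
        assert got == (None, None, True)

    def test_censored_values_route_to_range_split(self):
        assert split_numeric_unit(">89").flagged
        assert split_numeric_range(">89") == (89.0, None)
        assert split_numeric_range("<5") == (None, 5.0)
        assert split_numeric_range("40-49") == (40.0, 49.0)


@pytest.fixture
def treatment_map():
    """The diabetes-drug mapping including two brand names of one generic."""
    rows = [("metformin", "Metformin"), ("sitagliptin", "Sitagliptin"),
            ("lantus", "Insulin Glargine"), ("solostar", "Insulin Glargine"),
            ("novorapid", "Insulin Aspart")]
    return CurationMap("treatment", [CurationMapEntry(o, c) for o, c in rows])


class TestApplyCurationMap:
    def test_brand_names_deduplicate_to_generic(self, treatment_map):
        got = apply_curation_map("metformin;sitagliptin;lantus;solostar;novorapid",
                                 treatment_map)
        assert got.terms == "Metformin;Sitagliptin;Insulin Glargine;Insulin Aspart"
        assert got.unmapped == []

    def test_identity_map_passthrough(self):
        got = apply_curation_map("a;b", CurationMap.identity("x"))
        assert got.terms == "a;b" and got.unmapped == ["a", "b"]

    def test_partial_map_passthrough_reports_unmapped(self):
        cmap = CurationMap("x", [CurationMapEntry("a", "A")])
        got = apply_curation_map("a;zzz", cmap)
        assert got.terms == "A;zzz" and got.unmapped == ["zzz"]

    def test_unmapped_na_policy_drops(self):
        cmap = CurationMap("x", [CurationMapEntry("a", "A")])
        got = apply_curation_map("a;zzz", cmap, unmapped="na")
        assert got.terms == "A" and got.unmapped == ["zzz"]

    def test_na_cell_all_na(self, treatment_map):
        got = apply_curation_map(None, treatment_map)
        assert got == (None, None, None, [])

    def test_lookup_is_trim_casefold(self, treatment_map):
        assert apply_curation_map(" LANTUS ", treatment_map).terms == "Insulin Glargine"

    def test_idempotent_when_values_disjoint_from_keys(self, treatment_map):
        once = apply_curation_map("metformin;lantus", treatment_map).terms
        twice = apply_curation_map(once, treatment_map).terms
        assert once == twice

    def test_ids_aligned_to_surviving_terms(self):
        cmap = CurationMap("x", [
            CurationMapEntry("a", "A", "P:1", "P"),
            CurationMapEntry("b", "A", "P:1", "P"),
            CurationMapEntry("c", "C", "P:3", "P")])
        got = apply_curation_map("a;b;c", cmap)
        assert got.terms == "A;C" and got.ids == "P:1;P:3"

    def test_semicolon_in_map_key_rejected(self):
        with pytest.raises(ValueError, match="';'"):
            CurationMap("x", [CurationMapEntry("a;b", "A")])

    def test_duplicate_normalized_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CurationMap("x", [CurationMapEntry("A", "x"), CurationMapEntry("a ", "y")])


class TestHarmonizeAttribute:
    def test_first_nonna_source_wins_provenance(self):
        table = pd.DataFrame({"ancestry_raw": ["white"], "race": [None]})
        maps = {"ancestry_raw": CurationMap("ancestry_raw",
                                            [CurationMapEntry("white", "European")])}
        frame, conflicts = harmonize_attribute(table, "ancestry",
                                               ["ancestry_raw", "race"], maps)
        assert frame.at[0, "curated_ancestry"] == "European"
        assert frame.at[0, "curated_ancestry_source"] == "ancestry_raw"
        assert frame.at[0, "original_ancestry_value"] == "white"
        assert conflicts == []

    def test_granularity_collapses_to_most_specific(self, neoplasm_graph):
        table = pd.DataFrame({"a": ["tumor"], "b": ["primary tumor"]})
        maps = {"a": CurationMap("a", [CurationMapEntry("tumor", "Neoplasm", "N:1", "N")]),
                "b": CurationMap("b", [CurationMapEntry("primary tumor",
                                                        "Primary Neoplasm", "N:2", "N")])}
        frame, _ = harmonize_attribute(table, "sample_type", ["a", "b"], maps,
                                       graph=neoplasm_graph, kind="single")
        assert frame.at[0, "curated_sample_type"] == "Primary Neoplasm"

    def test_all_sources_na(self):
        table = pd.DataFrame({"a": [None], "b": [None]})
        frame, _ = harmonize_attribute(table, "x", ["a", "b"], {})
        assert frame.at[0, "curated_x"] is None
        assert frame.at[0, "curated_x_source"] is None

    def test_single_valued_sibling_conflict_routed_not_dropped(self, neoplasm_graph):
        table = pd.DataFrame({"a": ["primary tumor"], "b": ["met tumor"]})
        maps = {"a": CurationMap("a", [CurationMapEntry("primary tumor",
                                                        "Primary Neoplasm", "N:2", "N")]),
                "b": CurationMap("b", [CurationMapEntry("met tumor",
                                                        "Metastatic Neoplasm", "N:3", "N")])}
        frame, conflicts = harmonize_attribute(table, "sample_type", ["a", "b"], maps,
                                               graph=neoplasm_graph, kind="single")
        assert frame.at[0, "curated_sample_type"] is None
        assert len(conflicts) == 1 and conflicts[0]["attribute"] == "sample_type"

    def test_missing_source_column_errors(self):
        with pytest.raises(KeyError, match="absent"):
            harmonize_attribute(pd.DataFrame({"a": ["x"]}), "y", ["a", "gone"], {})

    def test_missing_map_errors_without_passthrough(self):
        with pytest.raises(ValueError, match="pass-through"):
            harmonize_attribute(pd.DataFrame({"a": ["x"]}), "y", ["a"], {},
                                unmapped="na")

    def test_never_invents_tokens(self, treatment_map):
        """Every curated token is a map value or a pass-through original."""
        table = pd.DataFrame({"treatment": ["lantus;aspirin", "novorapid", None]})
        frame, _ = harmonize_attribute(table, "treatment", ["treatment"],
                                       {"treatment": treatment_map})
        legal = ({e.curated_ontology_term for e in treatment_map.entries.values()}
                 | {"aspirin"})
        for cell in frame["curated_treatment"].dropna():
            assert set(cell.split(";")) <= legal


class TestUnmappedReport:
    def test_fully_mapped_is_empty(self, treatment_map):
        table = pd.DataFrame({"treatment": ["lantus", "metformin", None]})
        report = unmapped_report(table, {"treatment": ["treatment"]},
                                 {"treatment": treatment_map})
        assert report.empty

    def test_counts_sorted_descending(self, treatment_map):
        table = pd.DataFrame({"treatment": ["aspirin", "aspirin;ibuprofen",
                                            "aspirin", None]})
        report = unmapped_report(table, {"treatment": ["treatment"]},
                                 {"treatment": treatment_map})
        assert list(report["value"]) == ["aspirin", "ibuprofen"]
        assert list(report["count"]) == [3, 1]

    def test_na_only_column_empty(self):
        table = pd.DataFrame({"x": [None, None]})
        assert unmapped_report(table, {"x": ["x"]}, {}).empty

    def test_suggestions_come_from_map_vocabulary(self, treatment_map):
        table = pd.DataFrame({"treatment": ["Metformine"]})
        report = unmapped_report(table, {"treatment": ["treatment"]},
                                 {"treatment": treatment_map}, suggest=True)
        assert report.at[0, "suggestion"] == "Metformin"
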