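import numpy as np
import pandas as pd
import pytest

from conftest import brute_relatives, random_dag
from metaharm.query import (canonical_multi, expand_query, gather_meta,
                            spread_meta, tree_filter)


class TestExpandQuery:
    def test_root_expansion_covers_descendant_labels(self, diamond_graph):
        exp = expand_query(diamond_graph, ["Alpha"])
        assert {"alpha", "beta", "gamma", "delta"} <= exp.expanded

    def test_synonyms_included(self, diamond_graph):
        exp = expand_query(diamond_graph, ["Gamma"])
        assert "ace inhibitor" in exp.expanded
        assert exp.provenance["ace inhibitor"] == "synonym"

    def test_curie_seed_accepted(self, diamond_graph):
        exp = expand_query(diamond_graph, ["T:B"])
        assert "delta" in exp.expanded

    def test_unresolvable_term_contributes_itself(self, diamond_graph):
        with pytest.warns(UserWarning, match="no query term resolved"):
            exp = expand_query(diamond_graph, ["xyz"])
        assert exp.expanded == {"xyz"}

    def test_seed_always_in_expansion(self, diamond_graph):
        for term in ("Alpha", "nonsense", "T:D"):
            exp = expand_query(diamond_graph, [term, "Alpha"])
            assert term.casefold() in exp.expanded


@pytest.fixture
def disease_table(diamond_graph):
    return pd.DataFrame({
        "curation_id": ["s:1", "s:2", "s:3", "s:4"],
        "disease": ["Delta", "Gamma", None, "Beta;Gamma"],
    })


class TestTreeFilter:
    def test_descendant_matching_supersets_exact(self, diamond_graph, disease_table):
        exact = disease_table[disease_table["disease"] == "Beta"]
        hier = tree_filter(disease_table, "disease", ["Beta"], diamond_graph)
        # Delta is a subtype of Beta: hierarchy-aware search finds more
        assert set(exact["curation_id"]) <= set(hier["curation_id"])
        assert set(hier["curation_id"]) == {"s:1", "s:4"}

    def test_all_logic_requires_every_term(self, diamond_graph, disease_table):
        got = tree_filter(disease_table, "disease", ["Beta", "Gamma"],
                          diamond_graph, logic="all")
        assert list(got["curation_id"]) == ["s:4"]

    def test_all_logic_disjoint_terms_one_token_row(self, diamond_graph, disease_table):
        got = tree_filter(disease_table.iloc[:1], "disease", ["Delta", "Gamma"],
                          diamond_graph, logic="all")
        assert got.empty

    def test_na_cells_never_match(self, diamond_graph, disease_table):
        got = tree_filter(disease_table, "disease", ["Alpha"], diamond_graph)
        assert "s:3" not in set(got["curation_id"])

    def test_monotone_in_query_terms(self, diamond_graph, disease_table):
        small = tree_filter(disease_table, "disease", ["Delta"], diamond_graph)
        large = tree_filter(disease_table, "disease", ["Delta", "Gamma"], diamond_graph)
        assert set(small["curation_id"]) <= set(large["curation_id"])

    def test_unknown_attribute_errors(self, diamond_graph, disease_table):
        with pytest.raises(KeyError):
            tree_filter(disease_table, "nope", ["Alpha"], diamond_graph)

    def test_equals_brute_force_scan_on_random_dags(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            g = random_dag(rng, max_nodes=25)
            ids = list(g.terms)
            labels = [g.terms[i].label for i in ids]
            cells = [";".join(rng.choice(labels,
                                         size=int(rng.integers(1, 3)),
                                         replace=False))
                     if rng.random() > 0.2 else None for _ in range(20)]
            table = pd.DataFrame({"x": cells})
            seed = ids[int(rng.integers(len(ids)))]
            # independent expansion: seed + oracle descendants, by label
            oracle_keys = {g.terms[seed].label.casefold(), seed.casefold()}
            for d in brute_relatives(g, seed, "descendants"):
                oracle_keys.add(g.terms[d].label.casefold())
                oracle_keys |= {s.casefold() for s in g.terms[d].synonyms}
            oracle_keys |= {s.casefold() for s in g.terms[seed].synonyms}
            expect = [i for i, c in enumerate(cells) if c and
                      {t.casefold() for t in c.split(";")} & oracle_keys]
            got = tree_filter(table, "x", [seed], g)
            assert list(got.index) == expect


class TestSpreadGather:
    def test_multi_spread_one_row_per_token(self):
        t = pd.DataFrame({"curation_id": ["s:1"], "treatment": ["Metformin;Aspirin"]})
        wide = spread_meta(t, "treatment", "multi")
        assert len(wide) == 2
        assert list(wide["treatment"]) == ["Metformin", "Aspirin"]
        assert set(wide["curation_id"]) == {"s:1"}

    def test_single_token_row_unchanged(self):
        t = pd.DataFrame({"curation_id": ["s:1"], "treatment": ["Metformin"]})
        assert len(spread_meta(t, "treatment", "multi")) == 1

    def test_composite_spread_to_named_columns(self):
        t = pd.DataFrame({"curation_id": ["s:1", "s:2"],
                          "biomarker": ["CRP:2.3;IL6:1.1", "CRP:0.4"]})
        wide = spread_meta(t, "biomarker", "composite")
        assert wide.at[0, "biomarker_CRP"] == "2.3"
        assert wide.at[0, "biomarker_IL6"] == "1.1"
        assert wide.at[1, "biomarker_IL6"] is None

    def test_malformed_composite_token_errors(self):
        t = pd.DataFrame({"curation_id": ["s:9"], "biomarker": ["CRP2.3"]})
        with pytest.raises(ValueError, match="s:9"):
            spread_meta(t, "biomarker", "composite")

    def test_gather_merges_rows_sharing_curation_id(self):
        t = pd.DataFrame({"curation_id": ["s:1", "s:1"], "x": ["a", "b"]})
        narrow = gather_meta(t, "x", "multi")
        assert list(narrow["x"]) == ["a;b"]

    def test_gather_disagreeing_context_errors(self):
        t = pd.DataFrame({"curation_id": ["s:1", "s:1"], "x": ["a", "b"],
                          "site": ["gut", "skin"]})
        with pytest.raises(ValueError, match="non-rectangular"):
            gather_meta(t, "x", "multi")

    def test_one_row_table_round_trips(self):
        t = pd.DataFrame({"curation_id": ["s:1"], "x": ["a"]})
        assert gather_meta(t, "x", "multi").equals(t)

    @pytest.mark.parametrize("kind", ["multi", "composite"])
    def test_gather_of_spread_is_canonical_identity(self, kind):
        rng = np.random.default_rng(2024)
        tokens = ["A", "B", "C", "D"]
        for _ in range(200):
            n = int(rng.integers(1, 6))
            cells = []
            for _ in range(n):
                if rng.random() < 0.15:
                    cells.append(None)
                    continue
                k = int(rng.integers(1, 4))
                picks = list(rng.choice(tokens, size=k, replace=False))
                if kind == "composite":
                    cells.append(";".join(f"{p}:{int(rng.integers(9))}" for p in picks))
                else:
                    cells.append(";".join(picks))
            t = pd.DataFrame({"curation_id": [f"s:{i}" for i in range(n)],
                              "ctx": [f"c{i}" for i in range(n)],
                              "attr": cells})
            if kind == "composite":
                # canonical composite order is global first-appearance of
                # feature names (the spread column order)
                order = []
                for c in cells:
                    for tok in (c or "").split(";"):
                        name = tok.split(":")[0]
                        if name and name not in order:
                            order.append(name)
                def canon(c):
                    if c is None:
                        return None
                    pairs = dict(tok.split(":", 1) for tok in c.split(";"))
                    return ";".join(f"{k}:{pairs[k]}" for k in order if k in pairs)
                canonical = t.assign(attr=[canon(c) for c in t["attr"]])
            else:
                canonical = t.assign(attr=[canonical_multi(c) for c in t["attr"]])
            back = gather_meta(spread_meta(t, "attr", kind), "attr", kind)
            if kind == "composite":
                back = back[canonical.columns]
            pd.testing.assert_frame_equal(back, canonical)
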