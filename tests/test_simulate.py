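import numpy as np
import pandas as pd
import pytest

from metaharm.model import AttributeSpec
from metaharm.simulate import (CorruptionConfig, corrupt_metadata,
                               make_clean_cohort, make_toy_ontology,
                               recover_cohort, recovery_report)

ROOT = "TOY:0000001"


def toy_specs():
    return [
        AttributeSpec("ancestry", kind="single", value_class="ontology-categorical",
                      dynamic_enum_nodes=[ROOT]),
        AttributeSpec("treatment", kind="multi", value_class="ontology-categorical",
                      dynamic_enum_nodes=[ROOT]),
        AttributeSpec("age", kind="single", value_class="free-text"),
    ]


class TestMakeToyOntology:
    def test_geometric_term_count(self):
        g, leaves = make_toy_ontology(depth=2, branching=3, seed=0)
        assert len(g) == 1 + 3 + 9
        assert len(leaves) == 9

    def test_same_seed_identical(self):
        a, _ = make_toy_ontology(depth=3, branching=2, seed=5)
        b, _ = make_toy_ontology(depth=3, branching=2, seed=5)
        assert {t.id: (t.label, frozenset(t.parents), frozenset(t.synonyms))
                for t in a.terms.values()} == \
               {t.id: (t.label, frozenset(t.parents), frozenset(t.synonyms))
                for t in b.terms.values()}

    def test_root_descendant_count(self):
        g, _ = make_toy_ontology(depth=2, branching=3, seed=0)
        assert len(g.descendants(ROOT)) == 12

    def test_multiple_prefixes_disjoint(self):
        g, _ = make_toy_ontology(depth=1, branching=2, prefixes=("AAA", "BBB"), seed=0)
        assert g.shared_ancestors({"AAA:0000002", "BBB:0000002"}).all == frozenset()


class TestMakeCleanCohort:
    @pytest.fixture
    def cohort(self):
        g, _ = make_toy_ontology(depth=2, branching=3, seed=1)
        return make_clean_cohort(10, 3, toy_specs(), g, seed=2,
                                 time_invariant=("ancestry",)), g

    def test_row_count(self, cohort):
        (table, _), _ = cohort
        assert len(table) == 30

    def test_time_invariant_constant_within_patient(self, cohort):
        (table, _), _ = cohort
        assert (table.groupby("participant_id")["ancestry"].nunique() == 1).all()

    def test_same_seed_identical(self):
        g, _ = make_toy_ontology(depth=2, branching=3, seed=1)
        a, _ = make_clean_cohort(5, 2, toy_specs(), g, seed=7)
        b, _ = make_clean_cohort(5, 2, toy_specs(), g, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_values_are_allowed_leaves(self, cohort):
        (table, _), g = cohort
        leaves = {g[t].label for t in g.descendants(ROOT) if not g.children(t)}
        for cell in table["treatment"]:
            assert set(cell.split(";")) <= leaves


class TestCorruptMetadata:
    @pytest.fixture
    def setting(self):
        g, _ = make_toy_ontology(depth=3, branching=3, seed=1)
        specs = toy_specs()
        clean, truth = make_clean_cohort(50, 3, specs, g, seed=2,
                                         time_invariant=("ancestry",))
        return g, specs, clean

    def test_all_rates_zero_is_identity(self, setting):
        g, specs, clean = setting
        cfg = CorruptionConfig(typo_rate=0, abbreviation_rate=0,
                               binary_encode_rate=0, dispersal_columns=1,
                               misplacement_rate=0, conflict_rate=0, seed=0)
        res = corrupt_metadata(clean, cfg, specs, g, time_invariant=("ancestry",))
        pd.testing.assert_frame_equal(res.messy, clean)
        assert res.log.empty

    def test_conflict_count_within_binomial_bounds(self, setting):
        g, specs, clean = setting
        cfg = CorruptionConfig(typo_rate=0, abbreviation_rate=0,
                               binary_encode_rate=0, dispersal_columns=1,
                               misplacement_rate=0, conflict_rate=0.2, seed=11)
        res = corrupt_metadata(clean, cfg, specs, g, time_invariant=("ancestry",))
        n = (res.log["kind"] == "conflict").sum()
        # 50 patients at rate 0.2: +-4 sigma of Binomial(50, 0.2)
        assert 0 < n <= 10 + 4 * np.sqrt(50 * 0.2 * 0.8)
        assert n == len(res.log)  # exactly one flip per affected patient

    def test_dispersal_partitions_non_na_cells(self, setting):
        g, specs, clean = setting
        cfg = CorruptionConfig(typo_rate=0, abbreviation_rate=0,
                               binary_encode_rate=0, dispersal_columns=3,
                               misplacement_rate=0, conflict_rate=0, seed=4)
        res = corrupt_metadata(clean, cfg, specs, g, time_invariant=("ancestry",),
                               dispersal_attribute="treatment")
        parts = [c for c in res.messy.columns if c.startswith("treatment__part")]
        assert len(parts) == 3
        assert "treatment" not in res.messy.columns
        filled = res.messy[parts].notna().sum(axis=1)
        assert (filled == clean["treatment"].notna().astype(int)).all()
        recovered = res.messy[parts].bfill(axis=1)[parts[0]]
        assert (recovered.fillna("") == clean["treatment"].fillna("")).all()

    def test_typos_logged_but_not_mapped(self, setting):
        g, specs, clean = setting
        cfg = CorruptionConfig(typo_rate=0.1, abbreviation_rate=0,
                               binary_encode_rate=0, dispersal_columns=1,
                               misplacement_rate=0, conflict_rate=0, seed=6)
        res = corrupt_metadata(clean, cfg, specs, g, time_invariant=("ancestry",))
        typos = res.log[res.log["kind"] == "typo"]
        assert len(typos) > 0 and not typos["recoverable"].any()
        for bad in typos["corrupted"]:
            for cmap in res.maps.values():
                assert cmap.lookup(bad) is None

    def test_bit_reproducible_under_seed(self, setting):
        g, specs, clean = setting
        cfg = CorruptionConfig(seed=9)
        a = corrupt_metadata(clean, cfg, specs, g, time_invariant=("ancestry",),
                             dispersal_attribute="treatment",
                             binary_attribute="treatment")
        b = corrupt_metadata(clean, cfg, specs, g, time_invariant=("ancestry",),
                             dispersal_attribute="treatment",
                             binary_attribute="treatment")
        pd.testing.assert_frame_equal(a.messy, b.messy)
        pd.testing.assert_frame_equal(a.log, b.log)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            CorruptionConfig(typo_rate=1.5)
        with pytest.raises(ValueError):
            CorruptionConfig(dispersal_columns=0)


class TestEndToEndRecovery:
    def test_full_recovery_outside_unrecoverable_set(self):
        """harmonize + consensus on corrupt(clean) equals clean on every cell
        not touched by a logged unrecoverable corruption."""
        g, _ = make_toy_ontology(depth=3, branching=3, seed=1)
        specs = toy_specs()
        clean, _ = make_clean_cohort(60, 3, specs, g, seed=2,
                                     time_invariant=("ancestry",))
        res = corrupt_metadata(clean, CorruptionConfig(seed=3), specs, g,
                               time_invariant=("ancestry",),
                               dispersal_attribute="treatment",
                               binary_attribute="treatment")
        recovered = recover_cohort(res, specs, g, time_invariant=("ancestry",))
        report = recovery_report(recovered, clean, res, specs)
        assert report["cells"] > 400
        assert report["fraction"] == 1.0, report["mismatches"][:5]
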