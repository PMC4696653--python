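import json
import random

import pytest

from semmerge import (
    Model,
    Variable,
    add_manual_mapping,
    annotations_equivalent,
    build_process_annotation,
    find_overlaps,
)
from semmerge.errors import OverlapError
from semmerge.overlap import brute_force_overlap_pairs
from semmerge import fixtures as fx


def _two_process_models(left_ann, right_ann):
    left = Model("L", "t", (
        Variable.domain("t", "second"),
        Variable.algebraic("jL", "millimolar_per_second", "1 + 0 * t", annotation=left_ann),
    ))
    right = Model("R", "t", (
        Variable.domain("t", "second"),
        Variable.algebraic("jR", "millimolar_per_second", "2 + 0 * t", annotation=right_ann),
    ))
    return left, right


class TestEquivalence:
    def test_identical_calcium_composites_match(self, suite):
        a = suite.E.get("Ca_i_E").annotation
        b = suite.C.get("Ca_i_C").annotation
        assert annotations_equivalent(a, b)

    def test_source_sink_swap_breaks_equivalence(self):
        fwd = build_process_annotation(
            fx.OPB_CHEM_FLOW, "fwd", sources=[(fx.CA_EXT, 1.0)], sinks=[(fx.CA_CYTO, 1.0)])
        assert annotations_equivalent(fwd, fwd)
        assert not annotations_equivalent(fwd, build_process_annotation(
            fx.OPB_CHEM_FLOW, "rev", sources=[(fx.CA_CYTO, 1.0)], sinks=[(fx.CA_EXT, 1.0)]))

    def test_current_vs_concentration_flow_distinct(self, suite):
        current = suite.E.get("i_b_Ca").annotation
        flux = suite.C.get("J_b_Ca").annotation
        assert current.participants == flux.participants
        assert not annotations_equivalent(current, flux)

    def test_custom_terms_never_match_across_models(self, suite):
        a = suite.C.get("CaTrpn_C").annotation
        b = suite.T.get("CaTrpn_T").annotation
        assert a == b  # structurally identical ...
        assert not annotations_equivalent(a, b)  # ... yet semantically opaque

    def test_cross_variant_comparison_false(self, suite):
        assert not annotations_equivalent(
            suite.E.get("Ca_i_E").annotation, suite.E.get("F_E").annotation)


class TestFindOverlaps:
    def test_pre_glue_manifest(self, suite):
        got = {(it.kind, *it.pair()) for it in find_overlaps(suite.E, suite.C).auto_items()}
        assert got == suite.manifest["E:C"]

    def test_post_glue_manifest_gains_background_current(self, suite):
        got = {(it.kind, *it.pair()) for it in find_overlaps(suite.E, suite.C_prime).auto_items()}
        assert got == suite.manifest["E:C_prime"]
        assert got - suite.manifest["E:C"] == {("process_property", "i_b_Ca", "i_b_Ca_C")}

    def test_volume_item_carries_conversion_factor(self, suite):
        item = find_overlaps(suite.E, suite.C).find("Vol_myo_E", "Vol_C")
        assert item.unit_mismatch and item.conversion_factor == 1e9

    def test_disjoint_annotations_leave_only_solution_domain(self, suite, decay_model):
        report = find_overlaps(decay_model, suite.T)
        assert [it.kind for it in report.items] == ["solution_domain"]

    def test_reflexivity(self, suite):
        report = find_overlaps(suite.E, suite.E)
        annotated = {v.name for v in suite.E.variables if v.annotation}
        assert {it.left_var for it in report.items if it.kind != "solution_domain"} == annotated
        assert all(it.left_var == it.right_var for it in report.items)

    def test_symmetry(self, suite):
        fwd = find_overlaps(suite.E, suite.C_prime)
        rev = find_overlaps(suite.C_prime, suite.E)
        assert {(it.kind, it.left_var, it.right_var) for it in fwd.items} == \
            {(it.kind, it.right_var, it.left_var) for it in rev.items}

    def test_repeated_runs_byte_identical(self, suite):
        a = json.dumps(find_overlaps(suite.E, suite.C_prime).to_json())
        b = json.dumps(find_overlaps(suite.E, suite.C_prime).to_json())
        assert a == b

    def test_within_model_duplicates_warned_and_excluded(self, suite):
        ann = suite.C.get("Ca_i_C").annotation
        dup = Model("dup", "t", (
            Variable.domain("t", "second"),
            Variable.constant("ca1", "millimolar", 1.0, annotation=ann),
            Variable.constant("ca2", "millimolar", 2.0, annotation=ann),
        ))
        report = find_overlaps(dup, suite.E)
        assert any("duplicate annotation" in w for w in report.warnings)
        assert [it.kind for it in report.items] == ["solution_domain"]


class TestManualMappings:
    def test_custom_term_pair_needs_manual_mapping(self, suite):
        ec = fx.merge_excitation_calcium(suite).merged
        report = find_overlaps(ec, suite.T)
        assert report.find("J_trpn", "d_trpn") is None
        report = add_manual_mapping(report, "J_trpn", "d_trpn")
        item = report.find("J_trpn", "d_trpn")
        assert item.origin == "manual" and not item.unit_mismatch

    def test_mapping_existing_auto_item_rejected(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        with pytest.raises(OverlapError, match="already an auto item"):
            add_manual_mapping(report, "Ca_i_E", "Ca_i_C")

    def test_unknown_variable_rejected(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        with pytest.raises(OverlapError):
            add_manual_mapping(report, "nope", "Ca_i_C")

    def test_incommensurable_manual_pair_flagged_without_factor(self, suite):
        report = add_manual_mapping(find_overlaps(suite.E, suite.C), "V_m", "Ca_i_C")
        item = report.find("V_m", "Ca_i_C")
        assert item.unit_mismatch and item.conversion_factor is None


class TestOracleEquivalence:
    def test_indexed_matches_brute_force_on_random_pairs(self):
        rng = random.Random(20260929)
        for _ in range(150):
            a = fx.random_annotated_model(rng.randrange(2, 50), rng.randrange(2**31))
            b = fx.random_annotated_model(rng.randrange(2, 50), rng.randrange(2**31))
            got = {it.pair() for it in find_overlaps(a, b).auto_items()
                   if it.kind != "solution_domain"}
            assert got == brute_force_overlap_pairs(a, b)

    def test_oracle_on_self_comparison(self):
        m = fx.random_annotated_model(30, 1234)
        got = {it.pair() for it in find_overlaps(m, m).auto_items()
               if it.kind != "solution_domain"}
        assert got == brute_force_overlap_pairs(m, m)
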