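import pytest

from semmerge import (
    ProcessParticipants,
    Singular,
    TermRef,
    build_entity_annotation,
    build_process_annotation,
    canonical_key,
    transfer_annotations,
)
from semmerge.annotation import annotation_from_json, annotation_to_json
from semmerge.errors import AnnotationError
from semmerge import fixtures as fx


class TestConstruction:
    def test_cytosolic_calcium_exemplar(self):
        ann = build_entity_annotation(
            fx.OPB_CONCENTRATION,
            [fx.CHEBI_CALCIUM, fx.FMA_CYTOSOL, fx.FMA_CARDIOMYOCYTE],
        )
        assert ann.property.ontology == "OPB"
        assert [t.label for t in ann.entity.chain] == \
            ["calcium(2+)", "Cytosol", "Cardiac myocyte"]
        assert not ann.contains_custom

    def test_custom_entity_flags_contains_custom(self):
        ann = build_entity_annotation(
            fx.OPB_CONCENTRATION, [fx.CUSTOM_CA_TRPN, fx.FMA_CYTOSOL])
        assert ann.contains_custom

    def test_non_opb_property_rejected(self):
        with pytest.raises(AnnotationError, match="OPB"):
            build_entity_annotation(fx.FMA_CYTOSOL, [fx.CHEBI_CALCIUM])

    def test_empty_chain_rejected(self):
        with pytest.raises(AnnotationError):
            build_entity_annotation(fx.OPB_CONCENTRATION, [])

    def test_custom_term_needs_label(self):
        with pytest.raises(AnnotationError):
            TermRef("CUSTOM", "", "")

    def test_participant_roles_must_be_disjoint(self):
        with pytest.raises(AnnotationError, match="disjoint"):
            ProcessParticipants(
                sources=((fx.CA_CYTO, 1.0),),
                sinks=((fx.CA_CYTO, 1.0),),
            )

    def test_multipliers_must_be_positive(self):
        with pytest.raises(AnnotationError):
            ProcessParticipants(sources=((fx.CA_CYTO, 0.0),))


class TestCanonicalKey:
    def test_independent_copies_collide(self):
        a = build_entity_annotation(
            fx.OPB_CONCENTRATION, [fx.CHEBI_CALCIUM, fx.FMA_CYTOSOL, fx.FMA_CARDIOMYOCYTE])
        b = build_entity_annotation(
            fx.OPB_CONCENTRATION, [fx.CHEBI_CALCIUM, fx.FMA_CYTOSOL, fx.FMA_CARDIOMYOCYTE])
        assert canonical_key(a) == canonical_key(b)

    def test_reference_term_labels_do_not_matter(self):
        variant = TermRef("CHEBI", "CHEBI:29108", "Ca2+ ion")
        a = build_entity_annotation(fx.OPB_CONCENTRATION, [fx.CHEBI_CALCIUM])
        b = build_entity_annotation(fx.OPB_CONCENTRATION, [variant])
        assert canonical_key(a) == canonical_key(b)

    def test_source_sink_swap_changes_key(self):
        fwd = build_process_annotation(
            fx.OPB_CHEM_FLOW, "fwd", sources=[(fx.CA_EXT, 1.0)], sinks=[(fx.CA_CYTO, 1.0)])
        rev = build_process_annotation(
            fx.OPB_CHEM_FLOW, "rev", sources=[(fx.CA_CYTO, 1.0)], sinks=[(fx.CA_EXT, 1.0)])
        assert canonical_key(fwd) != canonical_key(rev)

    def test_process_name_is_ignored(self):
        a = build_process_annotation(fx.OPB_CHEM_FLOW, "uptake", sources=[(fx.CA_CYTO, 1.0)])
        b = build_process_annotation(fx.OPB_CHEM_FLOW, "removal", sources=[(fx.CA_CYTO, 1.0)])
        assert canonical_key(a) == canonical_key(b)

    def test_stoichiometry_matters(self):
        a = build_process_annotation(fx.OPB_CHEM_FLOW, "p", sources=[(fx.CA_CYTO, 1.0)])
        b = build_process_annotation(fx.OPB_CHEM_FLOW, "p", sources=[(fx.CA_CYTO, 2.0)])
        assert canonical_key(a) != canonical_key(b)

    def test_custom_keys_are_model_scoped(self):
        ann = build_entity_annotation(
            fx.OPB_CONCENTRATION, [TermRef("CUSTOM", "", "diadic space")])
        assert canonical_key(ann, scope="A") != canonical_key(ann, scope="B")
        assert canonical_key(ann, scope="A") == canonical_key(ann, scope="A")

    def test_stable_across_serialization_round_trip(self, suite):
        for m in suite.models().values():
            for v in m.variables:
                if v.annotation is None:
                    continue
                again = annotation_from_json(annotation_to_json(v.annotation))
                assert canonical_key(again, scope=m.name) == canonical_key(v.annotation, scope=m.name)
                assert again == v.annotation


class TestSerialization:
    def test_singular_round_trip(self):
        ann = Singular(fx.OPB_FARADAY)
        assert annotation_from_json(annotation_to_json(ann)) == ann

    def test_process_round_trip_preserves_roles(self):
        ann = build_process_annotation(
            fx.OPB_CHARGE_FLOW, "bg",
            sources=[(fx.CA_EXT, 1.0)], sinks=[(fx.CA_CYTO, 2.0)], mediators=[fx.MEMBRANE])
        again = annotation_from_json(annotation_to_json(ann))
        assert again == ann
        assert again.participants.key() == ann.participants.key()

    def test_unknown_type_rejected(self):
        with pytest.raises(AnnotationError):
            annotation_from_json({"type": "mystery"})


class TestTransfer:
    def test_transfer_to_parameter_variant(self, suite):
        updated, report = transfer_annotations(suite.E, suite.E_epi)
        source_anns = {v.name: v.annotation for v in suite.E.variables if v.annotation}
        target_anns = {v.name: v.annotation for v in updated.variables if v.annotation}
        assert target_anns == source_anns
        assert sorted(report.transferred) == sorted(source_anns)
        assert report.skipped == [] and report.unmatched == []

    def test_idempotent(self, suite):
        once, _ = transfer_annotations(suite.E, suite.E_epi)
        twice, report = transfer_annotations(suite.E, once)
        assert twice == once
        assert report.transferred == []
        assert sorted(report.skipped) == sorted(
            v.name for v in suite.E.variables if v.annotation)

    def test_empty_source_is_identity(self, suite):
        updated, report = transfer_annotations(suite.E_epi, suite.E)
        assert updated == suite.E
        assert report.transferred == [] and report.skipped == []

    def test_transfer_onto_itself_is_identity(self, suite):
        updated, report = transfer_annotations(suite.E, suite.E)
        assert updated == suite.E
        assert report.transferred == []
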