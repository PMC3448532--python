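"""Distributed documents: parsing, flattening, combining, verification."""

import pytest

from minidol.core import (Asymmetric, Atomic, LogicId, Ontology, Signature,
                          SubClassOf)
from minidol.dol import (AlignmentCorrespondence, CircumscriptionLink,
                         DistributedOntology, InterpretationLink, combine,
                         flatten, parse_distributed, verify_document)
from minidol.errors import CombineError, LinkError
from minidol.fixtures import build_her2, fixture_text
from minidol.reasoner import entails


class TestParseDistributed:
    def test_mereology_document_structure(self, mereology):
        assert len(mereology.modules) == 6
        assert set(mereology.modules) == {
            "Taxonomy", "ELParthood", "ProperParthood", "Parthood",
            "FOLParthood", "ClassicalExtensionalParthood"}
        links = [l for l in mereology.links
                 if isinstance(l, InterpretationLink)]
        assert len(links) == 1
        assert links[0].name == "TaxonomyToELParthood"

    def test_singleton_document(self):
        doc = parse_distributed("distributed-ontology D\n"
                                "logic DL ontology Solo =\nClass A")
        assert list(doc.modules) == ["Solo"]
        assert doc.links == []

    def test_her2_document_structure(self, her2_doc):
        assert list(her2_doc.modules) == ["HER2"]
        assert her2_doc.modules["HER2"].imports == [("ProperParthood", None)]
        circ = [l for l in her2_doc.links
                if isinstance(l, CircumscriptionLink)]
        assert len(circ) == 1
        assert len(circ[0].implied) == 2

    def test_dangling_import_raises_link_error(self):
        with pytest.raises(LinkError):
            parse_distributed("distributed-ontology D\n"
                              "logic DL ontology A = Missing then\nClass C")

    def test_import_cycle_rejected(self):
        text = ("distributed-ontology D\n"
                "logic DL ontology A = B then\nClass C1\n"
                "logic DL ontology B = A then\nClass C2\n")
        with pytest.raises(LinkError):
            parse_distributed(text)


class TestFlatten:
    def test_fol_parthood_lives_in_fol_with_translated_axioms(self,
                                                              mereology):
        flat = flatten(mereology, "FOLParthood")
        assert flat.logic == LogicId.FOL
        # transitivity, asymmetry, subproperty, Atom and overlap all
        # arrive as first-order sentences
        assert len(flat.axioms) >= 8
        assert ("Ov", 2) in flat.signature.predicates
        assert ("isPartOf", 2) in flat.signature.predicates

    def test_no_imports_flattens_to_itself(self, mereology):
        flat = flatten(mereology, "Taxonomy")
        mod = mereology.modules["Taxonomy"]
        assert flat.logic == mod.logic
        assert flat.axioms == mod.axioms

    def test_her2_inherits_asymmetry_in_dl(self, her2):
        assert her2.logic == LogicId.DL
        assert Asymmetric("isProperPartOf") in her2.axioms

    def test_flatten_is_idempotent(self, mereology):
        flat = flatten(mereology, "ProperParthood")
        doc = DistributedOntology(name="F",
                                  modules={"ProperParthood": flat})
        again = flatten(doc, "ProperParthood")
        assert again.logic == flat.logic
        assert again.axioms == flat.axioms


class TestCombine:
    def _pair(self):
        o1 = Ontology("o1", LogicId.DL, Signature(concepts={"A", "B"}),
                      [SubClassOf(Atomic("A"), Atomic("B"))])
        o2 = Ontology("o2", LogicId.DL, Signature(concepts={"Bp", "C"}),
                      [SubClassOf(Atomic("Bp"), Atomic("C"))])
        return o1, o2

    def test_singleton_with_empty_alignment_is_identity(self):
        o1, _ = self._pair()
        out = combine([o1], [])
        assert out.axioms == o1.axioms
        assert out.signature.concepts == o1.signature.concepts

    def test_synonym_identification_enables_entailment(self):
        o1, o2 = self._pair()
        merged = combine([o1, o2],
                         [AlignmentCorrespondence("B", "Bp", "synonym", 1.0)])
        assert "Bp" not in merged.signature.concepts
        verdict = entails(merged, SubClassOf(Atomic("A"), Atomic("C")), 3)
        assert verdict.holds

    def test_synonym_merge_of_anatomy_terms(self):
        breast = Ontology("nci", LogicId.DL,
                          Signature(concepts={"Breast", "Organ"}),
                          [SubClassOf(Atomic("Breast"), Atomic("Organ"))])
        mouse = Ontology("ma", LogicId.DL,
                         Signature(concepts={"mammary_gland", "Gland"}),
                         [SubClassOf(Atomic("mammary_gland"),
                                     Atomic("Gland"))])
        merged = combine(
            [breast, mouse],
            [AlignmentCorrespondence("Breast", "mammary_gland",
                                     "synonym", 1.0)])
        # both names' axioms now constrain the single canonical concept
        v1 = entails(merged, SubClassOf(Atomic("Breast"), Atomic("Organ")),
                     3)
        v2 = entails(merged, SubClassOf(Atomic("Breast"), Atomic("Gland")),
                     3)
        assert v1.holds and v2.holds

    def test_associative_up_to_renaming_on_synonym_alignments(self):
        o1, o2 = self._pair()
        o3 = Ontology("o3", LogicId.DL, Signature(concepts={"C", "D"}),
                      [SubClassOf(Atomic("C"), Atomic("D"))])
        corr = [AlignmentCorrespondence("B", "Bp", "synonym", 1.0)]
        left = combine([combine([o1, o2], corr), o3], [])
        right = combine([o1, combine([o2, o3], [])], corr)
        assert set(map(repr, left.axioms)) == set(map(repr, right.axioms))
        assert left.signature.concepts == right.signature.concepts

    def test_confidence_never_affects_verdicts(self):
        o1, o2 = self._pair()
        goal = SubClassOf(Atomic("A"), Atomic("C"))
        results = set()
        for conf in (0.0, 0.3, 1.0):
            merged = combine([o1, o2],
                             [AlignmentCorrespondence("B", "Bp", "synonym",
                                                      conf)])
            results.add(entails(merged, goal, 3).status)
        assert len(results) == 1

    def test_subsumes_and_part_of_relations_add_axioms(self):
        o1, o2 = self._pair()
        merged = combine([o1, o2],
                         [AlignmentCorrespondence("A", "C", "subsumes", 1.0)])
        assert SubClassOf(Atomic("A"), Atomic("C")) in merged.axioms
        merged2 = combine([o1, o2],
                          [AlignmentCorrespondence("A", "C", "part_of", 0.9)])
        assert "isPartOf" in merged2.signature.roles

    def test_category_clash_raises(self):
        o1 = Ontology("o1", LogicId.DL, Signature(concepts={"A"}), [])
        o2 = Ontology("o2", LogicId.DL, Signature(roles={"r"}), [])
        with pytest.raises(CombineError):
            combine([o1, o2], [AlignmentCorrespondence("A", "r", "synonym",
                                                       1.0)])

    def test_confidence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AlignmentCorrespondence("a", "b", "synonym", 1.5)

    def test_alignment_loaded_from_tab_delimited_file(self, tmp_path):
        from minidol.dol import load_alignment
        path = tmp_path / "align.tsv"
        path.write_text("# source\ttarget\trelation\tconfidence\n"
                        "Breast\tmammary_gland\tsynonym\t1.0\n"
                        "Lobule\tBreast\tpart_of\t0.8\n", encoding="utf-8")
        corrs = load_alignment(path)
        assert len(corrs) == 2
        assert corrs[0].relation == "synonym"
        assert corrs[1].confidence == 0.8


class TestVerifyDocument:
    def test_mereology_passes_at_bound_4(self, mereology):
        report = verify_document(mereology, 4)
        assert report.passed
        kinds = {(i.kind, i.name) for i in report.items}
        assert ("interpretation", "TaxonomyToELParthood") in kinds
        assert ("consistency", "ClassicalExtensionalParthood") in kinds

    def test_her2_implies_verified_circumscriptively(self, her2_doc):
        report = verify_document(her2_doc, 5)
        assert report.passed
        implies_items = [i for i in report.items if i.kind == "implies"]
        assert len(implies_items) == 2

    def test_false_implies_fails_with_countermodel(self):
        doc = build_her2("reconciled")
        link = next(l for l in doc.links
                    if isinstance(l, CircumscriptionLink))
        from minidol.core import ClassAssertion
        link.implied.append(ClassAssertion(Atomic("HER2+_Tissue"), "Y"))
        report = verify_document(doc, 4)
        assert not report.passed
        failed = [i for i in report.items if not i.passed]
        assert len(failed) == 1
        assert failed[0].verdict.witness is not None
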