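"""Finite-model satisfaction, signatures and profile checking."""

import itertools

import pytest

from minidol.core import (And, Asymmetric, Atomic, Bottom, ClassAssertion,
                          DisjointClasses, FiniteInterpretation, LogicId,
                          Nominal, Ontology, Or, Signature, Some, SubClassOf,
                          Transitive, check_profile, concept_extension,
                          satisfies)
from minidol.errors import BoundExceededError, SignatureClashError
from minidol.core import ExistsP, ForallP, PredAtom, Var


def interp(n, **kw):
    return FiniteInterpretation(domain=tuple(range(n)), **kw)


class TestSatisfaction:
    def test_symmetric_pair_violates_asymmetry(self):
        i = interp(2, role_ext={"isPartOf": {(0, 1), (1, 0)}})
        assert not satisfies(i, Asymmetric("isPartOf"))
        i2 = interp(2, role_ext={"isPartOf": {(0, 1)}})
        assert satisfies(i2, Asymmetric("isPartOf"))

    def test_reflexive_pair_violates_asymmetry(self):
        i = interp(1, role_ext={"r": {(0, 0)}})
        assert not satisfies(i, Asymmetric("r"))

    def test_shared_element_violates_translated_disjointness(self):
        # S and T overlap on one element: S [= not T fails as S n T [= Bottom
        i = interp(2, concept_ext={"S": {0}, "T": {0}})
        ax = SubClassOf(And((Atomic("S"), Atomic("T"))), Bottom())
        assert not satisfies(i, ax)
        i2 = interp(2, concept_ext={"S": {0}, "T": {1}})
        assert satisfies(i2, ax)

    def test_her2_positive_tissue_assertion(self):
        i = interp(2, concept_ext={"Tissue": {0}, "HER2_Positive": {1}},
                   role_ext={"hasHER2Score": {(0, 1)}},
                   indiv={"X": 0, "3+": 1})
        ax = ClassAssertion(
            And((Atomic("Tissue"), Some("hasHER2Score", Nominal(("3+",))))),
            "X")
        assert satisfies(i, ax)
        # move the score edge away and the assertion fails
        i.role_ext["hasHER2Score"] = frozenset()
        assert not satisfies(i, ax)

    def test_taxonomy_union_subsumption_matches_set_containment(self):
        """tau(S v T v AR v PD -> PT) holds iff the union of the category
        extensions is contained in PT's — checked by brute force over all
        interpretations with domains of size <= 3 (two concepts extended,
        the others empty, which covers the containment geometry)."""
        ax = SubClassOf(Or((Atomic("S"), Atomic("T"), Atomic("AR"),
                            Atomic("PD"))), Atomic("PT"))
        for n in (1, 2, 3):
            dom = tuple(range(n))
            subsets = [frozenset(c) for r in range(n + 1)
                       for c in itertools.combinations(dom, r)]
            for s_ext, pt_ext in itertools.product(subsets, subsets):
                i = interp(n, concept_ext={"S": s_ext, "T": s_ext,
                                           "AR": frozenset(),
                                           "PD": frozenset(), "PT": pt_ext})
                union = s_ext  # S and T share s_ext; AR, PD empty
                assert satisfies(i, ax) == (union <= pt_ext)

    def test_second_order_bound_refused(self):
        i = interp(9)
        f = ForallP(("X",), PredAtom(Var("X"), (Var("x"),)))
        with pytest.raises(BoundExceededError):
            satisfies(i, ForallP(("X",), ExistsP(("Y",), f)), so_bound=8)


class TestSignature:
    def test_category_clash_detected(self):
        sig = Signature(concepts={"A"}, roles={"A"})
        with pytest.raises(SignatureClashError):
            sig.validate()

    def test_union_preserves_disjointness(self):
        a = Signature(concepts={"A"})
        b = Signature(roles={"r"}, individuals={"x"})
        u = a.union(b)
        assert u.concepts == {"A"} and u.roles == {"r"}


class TestProfile:
    def test_expdl_module_flagged(self, flat):
        violations = check_profile(flat["Parthood"])
        assert violations
        assert all(v.role == "isProperPartOf" for v in violations)
        kinds = {v.kind for v in violations}
        assert "transitive-asymmetric" in kinds

    def test_all_other_mereology_modules_clean(self, flat):
        for name in ("Taxonomy", "ELParthood", "ProperParthood"):
            assert check_profile(flat[name]) == []

    def test_synthetic_transitive_asymmetric_role(self):
        ont = Ontology("t", LogicId.EXPDL, Signature(roles={"r"}),
                       [Transitive("r"), Asymmetric("r")])
        violations = check_profile(ont)
        assert len(violations) == 1
        assert violations[0].role == "r"

    def test_chain_via_self_composition_counts_as_transitive(self):
        from minidol.core import SubPropertyChain
        ont = Ontology("t", LogicId.EXPDL, Signature(roles={"r"}),
                       [SubPropertyChain(("r", "r"), "r"), Asymmetric("r")])
        assert any(v.kind == "transitive-asymmetric"
                   for v in check_profile(ont))


def test_concept_extension_evaluates_set_theoretically():
    i = interp(3, concept_ext={"A": {0, 1}, "B": {1, 2}},
               role_ext={"r": {(0, 1), (2, 0)}})
    assert concept_extension(i, And((Atomic("A"), Atomic("B")))) == {1}
    assert concept_extension(i, Some("r", Atomic("B"))) == {0}
    assert satisfies(i, DisjointClasses((Atomic("A"), Atomic("B")))) is False


def test_interpretation_json_round_trips_values():
    i = interp(2, concept_ext={"A": frozenset({0})}, indiv={"a": 1})
    d = i.to_dict()
    assert d["domain"] == [0, 1]
    assert d["concept_ext"]["A"] == [0]
    assert d["indiv"] == {"a": 1}
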