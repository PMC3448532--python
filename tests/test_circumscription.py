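"""The circumscription pre-order and circumscriptive entailment."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from minidol.core import (Atomic, ClassAssertion, FiniteInterpretation,
                          LogicId, Nominal, Ontology, Or, Signature, Some,
                          SubClassOf, satisfies, satisfies_all)
from minidol.circumscription import (CircumscriptionSpec, circ_entails,
                                     minimal_models, preferred,
                                     strictly_preferred)
from minidol.dol import CircumscriptionLink
from minidol.fixtures import GeneratorConfig, random_ontology
from minidol.reasoner import entails


def interp(n, **kw):
    return FiniteInterpretation(domain=tuple(range(n)), **kw)


SPEC = CircumscriptionSpec(minimised=frozenset({"M"}),
                           varying=frozenset({"V"}))


class TestPreOrder:
    def test_reflexive(self):
        i = interp(2, concept_ext={"M": {0}, "V": {1}, "F": {0}})
        assert preferred(i, i, SPEC)
        assert not strictly_preferred(i, i, SPEC)

    def test_strict_on_proper_inclusion(self):
        i = interp(2, concept_ext={"M": frozenset(), "F": {0}})
        j = interp(2, concept_ext={"M": {1}, "F": {0}})
        assert preferred(i, j, SPEC) and strictly_preferred(i, j, SPEC)
        assert not preferred(j, i, SPEC)

    def test_fixed_difference_makes_structures_incomparable(self):
        i = interp(2, concept_ext={"M": set(), "F": {0}})
        j = interp(2, concept_ext={"M": set(), "F": {1}})
        assert not preferred(i, j, SPEC)
        assert not preferred(j, i, SPEC)

    def test_varying_difference_does_not_block_comparison(self):
        i = interp(2, concept_ext={"M": set(), "V": {0, 1}})
        j = interp(2, concept_ext={"M": {0}, "V": set()})
        assert preferred(i, j, SPEC)

    def test_role_extensions_move_freely(self):
        i = interp(2, concept_ext={"M": set()}, role_ext={"r": {(0, 1)}})
        j = interp(2, concept_ext={"M": {0}}, role_ext={"r": set()})
        assert preferred(i, j, SPEC)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_preorder_transitive_on_small_structures(self, data):
        """preferred() is reflexive and transitive on every comparability
        class over domains of size <= 3."""
        n = data.draw(st.integers(1, 3))
        subsets = [frozenset(c) for r in range(n + 1)
                   for c in itertools.combinations(range(n), r)]
        def struct():
            return interp(n, concept_ext={
                "M": data.draw(st.sampled_from(subsets)),
                "V": data.draw(st.sampled_from(subsets)),
                "F": frozenset()})
        a, b, c = struct(), struct(), struct()
        assert preferred(a, a, SPEC)
        if preferred(a, b, SPEC) and preferred(b, c, SPEC):
            assert preferred(a, c, SPEC)


class TestMinimalModels:
    def test_unconstrained_minimised_concept_is_empty(self):
        ont = Ontology("t", LogicId.DL, Signature(concepts={"A"}), [])
        spec = CircumscriptionSpec(minimised=frozenset({"A"}))
        models = minimal_models(ont, spec, 2)
        assert models
        assert all(not m.unary("A") for m in models)

    def test_disjunctive_assertion_minimises_to_exactly_one(self):
        ont = Ontology("t", LogicId.DL,
                       Signature(concepts={"A", "B"}, individuals={"a"}),
                       [ClassAssertion(Or((Atomic("A"), Atomic("B"))), "a")])
        spec = CircumscriptionSpec(minimised=frozenset({"A", "B"}))
        models = minimal_models(ont, spec, 2)
        assert models
        for m in models:
            in_a = m.indiv["a"] in m.unary("A")
            in_b = m.indiv["a"] in m.unary("B")
            assert in_a != in_b  # one or the other, never both

    def test_returned_models_admit_no_strictly_preferred_model(self):
        ont = random_ontology(GeneratorConfig(seed=7, max_concepts=2,
                                              max_roles=0,
                                              max_individuals=1, n_axioms=3))
        spec = CircumscriptionSpec(
            minimised=frozenset(sorted(ont.signature.concepts)[:1]))
        models = minimal_models(ont, spec, 2)
        for m in models:
            assert satisfies_all(m, ont.axioms)


class TestCircEntailment:
    def test_empty_spec_coincides_with_classical(self):
        rng = random.Random(42)
        for seed in range(15):
            ont = random_ontology(GeneratorConfig(seed=seed, max_concepts=3,
                                                  max_roles=1,
                                                  max_individuals=2,
                                                  n_axioms=6))
            concepts = sorted(ont.signature.concepts)
            goal = SubClassOf(Atomic(rng.choice(concepts)),
                              Atomic(rng.choice(concepts)))
            classical = entails(ont, goal, 2)
            circ = circ_entails(ont, CircumscriptionSpec(), goal, 2)
            assert circ.status == classical.status

    def test_conservativity_classical_implies_circumscriptive(self, her2,
                                                              her2_doc):
        link = _circ_link(her2_doc)
        goal = ClassAssertion(Atomic("Tissue"), "X")
        assert entails(her2, goal, 4).holds
        assert circ_entails(her2, link.spec, goal, 4).holds

    def test_grounding_matches_enumeration_oracle(self):
        ont = Ontology("t", LogicId.DL,
                       Signature(concepts={"A", "B"}, individuals={"a"}),
                       [ClassAssertion(Or((Atomic("A"), Atomic("B"))), "a")])
        spec = CircumscriptionSpec(minimised=frozenset({"A", "B"}))
        for goal in (ClassAssertion(Atomic("A"), "a"),
                     ClassAssertion(Or((Atomic("A"), Atomic("B"))), "a"),
                     SubClassOf(Atomic("A"), Atomic("B"))):
            vg = circ_entails(ont, spec, goal, 2, engine="ground")
            ve = circ_entails(ont, spec, goal, 2, engine="enumerate")
            assert vg.status == ve.status

    def test_refutation_witness_is_a_minimal_countermodel(self):
        ont = Ontology("t", LogicId.DL,
                       Signature(concepts={"A", "B"}, individuals={"a"}),
                       [ClassAssertion(Or((Atomic("A"), Atomic("B"))), "a")])
        spec = CircumscriptionSpec(minimised=frozenset({"A", "B"}))
        verdict = circ_entails(ont, spec, ClassAssertion(Atomic("A"), "a"),
                               2)
        assert verdict.status == "refuted"
        w = verdict.witness
        assert satisfies_all(w, ont.axioms)
        assert not satisfies(w, verdict.goal)
        assert not any(strictly_preferred(m, w, spec)
                       for m in minimal_models(ont, spec, 2))


class TestHER2Defaults:
    def test_unmeasured_tissue_defaults_to_normal(self, her2, her2_doc):
        link = _circ_link(her2_doc)
        goal = ClassAssertion(Atomic("Normal_Tissue"), "Y")
        assert not entails(her2, goal, 4).holds  # not classical (Fig-7 gap)
        assert circ_entails(her2, link.spec, goal, 4).holds

    def test_normality_retracted_when_evidence_added(self, her2, her2_doc):
        link = _circ_link(her2_doc)
        evidence = ClassAssertion(Some("hasHER2Score", Nominal(("3+",))),
                                  "Y")
        extended = her2.copy()
        extended.axioms = her2.axioms + [evidence]
        goal = ClassAssertion(Atomic("Normal_Tissue"), "Y")
        assert circ_entails(her2, link.spec, goal, 4).holds
        verdict = circ_entails(extended, link.spec, goal, 4)
        assert verdict.status == "refuted"


def _circ_link(doc):
    return next(l for l in doc.links if isinstance(l, CircumscriptionLink))
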