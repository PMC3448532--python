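"""Bounded model finding, entailment and classification."""

import random

import pytest

from minidol.core import (Atomic, Bottom, ClassAssertion, LogicId, Ontology,
                          RoleAssertion, Signature, SubClassOf, Top,
                          satisfies, satisfies_all)
from minidol.errors import InfeasibleBoundError
from minidol.fixtures import GeneratorConfig, random_ontology
from minidol.reasoner import (InconsistentOntologyError, classify, entails,
                              enumerate_models, find_model)
from minidol.translations import translate


class TestFindModel:
    def test_translated_taxonomy_consistent(self, flat):
        dl = translate(flat["Taxonomy"], LogicId.DL)
        model = find_model(dl, 4)
        assert model is not None
        assert satisfies_all(model, dl.axioms)

    def test_unsatisfiable_axiom_has_no_model(self):
        ont = Ontology("bad", LogicId.DL, Signature(concepts=set()),
                       [SubClassOf(Top(), Bottom())])
        for bound in (1, 2, 3):
            assert find_model(ont, bound) is None

    def test_mutual_proper_parthood_unsatisfiable(self, flat):
        ont = flat["ProperParthood"].copy()
        ont.signature.individuals |= {"a", "b"}
        ont.axioms = ont.axioms + [RoleAssertion("isProperPartOf", "a", "b"),
                                   RoleAssertion("isProperPartOf", "b", "a")]
        assert find_model(ont, 2, engine="ground") is None
        # confirmed by exhaustive enumeration at bound 2
        assert find_model(ont, 2, engine="enumerate") is None

    def test_infeasible_bound_error(self):
        from minidol.core import DifferentFrom
        ont = Ontology("d", LogicId.DL,
                       Signature(individuals={"a", "b", "c"}),
                       [DifferentFrom("a", "b"), DifferentFrom("b", "c"),
                        DifferentFrom("a", "c")])
        with pytest.raises(InfeasibleBoundError):
            find_model(ont, 2)
        assert find_model(ont, 3) is not None


class TestEntailment:
    def test_transitivity_chain_in_el(self, flat):
        ont = flat["ELParthood"].copy()
        ont.signature.individuals |= {"a", "b", "c"}
        ont.axioms = ont.axioms + [RoleAssertion("isPartOf", "a", "b"),
                                   RoleAssertion("isPartOf", "b", "c")]
        verdict = entails(ont, RoleAssertion("isPartOf", "a", "c"), 4)
        assert verdict.holds

    def test_subproperty_chain_inference_in_expdl(self, flat):
        ont = flat["Parthood"].copy()
        ont.signature.individuals |= {"a", "b", "c"}
        ont.axioms = ont.axioms + [
            RoleAssertion("isPartOf", "a", "b"),
            RoleAssertion("isProperPartOf", "b", "c")]
        verdict = entails(ont, RoleAssertion("isProperPartOf", "a", "c"), 3)
        assert verdict.holds

    def test_overlap_definition_and_symmetry(self, flat):
        from minidol.parser import parse_goal
        ont = flat["FOLParthood"].copy()
        ont.signature.individuals |= {"a", "b", "c"}
        ont.axioms = ont.axioms + [
            parse_goal(". isPartOf ( c a )", ont.logic, ont.signature),
            parse_goal(". isPartOf ( c b )", ont.logic, ont.signature)]
        ov = parse_goal(". Ov ( a b )", ont.logic, ont.signature)
        assert entails(ont, ov, 3).holds
        sym = parse_goal(". forall x y ( Ov ( x y ) implies Ov ( y x ) )",
                         ont.logic, ont.signature)
        assert entails(ont, sym, 3).holds

    def test_refutation_carries_verified_countermodel(self, flat):
        ont = flat["ProperParthood"]
        verdict = entails(ont, SubClassOf(Atomic("Atom"), Atomic("PT")), 3)
        assert verdict.status == "refuted"
        assert satisfies_all(verdict.witness, ont.axioms)
        assert not satisfies(verdict.witness, verdict.goal)

    def test_inconsistent_premises_reported(self):
        ont = Ontology("bad", LogicId.DL, Signature(concepts={"A"}),
                       [SubClassOf(Top(), Bottom())])
        verdict = entails(ont, SubClassOf(Atomic("A"), Atomic("A")), 2)
        assert verdict.status == "inconsistent_premises"

    def test_countermodel_monotone_in_bound(self):
        """A countermodel found at bound k is still one at every larger
        bound (the search space only grows)."""
        ont = Ontology("m", LogicId.DL, Signature(concepts={"A", "B"}), [])
        goal = SubClassOf(Atomic("A"), Atomic("B"))
        v2 = entails(ont, goal, 2)
        assert v2.status == "refuted"
        for bound in (3, 4):
            vk = entails(ont, goal, bound)
            assert vk.status == "refuted"
            # the small witness remains a countermodel
            assert satisfies_all(v2.witness, ont.axioms)
            assert not satisfies(v2.witness, goal)


class TestEngineAgreement:
    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_and_grounding_agree(self, seed):
        cfg = GeneratorConfig(seed=seed, max_concepts=3, max_roles=1,
                              max_individuals=2, n_axioms=6)
        ont = random_ontology(cfg)
        rng = random.Random(seed + 1_000_000)
        concepts = sorted(ont.signature.concepts)
        goal = SubClassOf(Atomic(rng.choice(concepts)),
                          Atomic(rng.choice(concepts)))
        assert (find_model(ont, 2, engine="enumerate") is None) == \
            (find_model(ont, 2, engine="ground") is None)
        assert entails(ont, goal, 2, engine="enumerate").status == \
            entails(ont, goal, 2, engine="ground").status

    def test_enumeration_yields_only_models(self):
        ont = random_ontology(GeneratorConfig(seed=3, max_concepts=2,
                                              max_roles=1,
                                              max_individuals=1, n_axioms=4))
        for m in enumerate_models(ont.axioms, ont.signature, 2):
            assert satisfies_all(m, ont.axioms)


class TestClassification:
    def test_her2_instance_types_match_monotone_baseline(self, her2):
        result = classify(her2, 6)
        assert "HER2+_Tissue" in result.instance_types["X"]
        y_types = result.instance_types.get("Y", set())
        assert "Normal_Tissue" not in y_types
        assert "HER2+_Tissue" not in y_types

    def test_her2_score_classes_under_ihc_score(self, her2):
        result = classify(her2, 6)
        for cls in ("HER2_Negative", "HER2_Borderline", "HER2_Positive"):
            assert (cls, "IHC_HER2_Score") in result.subsumptions

    def test_subsumptions_transitively_closed(self, her2):
        result = classify(her2, 6)
        subs = result.subsumptions
        for a, b in subs:
            for c, d in subs:
                if b == c:
                    assert (a, d) in subs or a == d

    def test_empty_ontology_classifies_empty(self):
        ont = Ontology("e", LogicId.DL, Signature(), [])
        result = classify(ont, 2)
        assert result.subsumptions == set()
        assert result.instance_types == {}

    def test_inconsistent_ontology_refused(self):
        ont = Ontology("bad", LogicId.DL, Signature(concepts={"A"}),
                       [SubClassOf(Top(), Bottom())])
        with pytest.raises(InconsistentOntologyError):
            classify(ont, 2)
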