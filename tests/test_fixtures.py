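"""The packaged case studies and the random-module generator."""

import pytest

from minidol.core import (Atomic, EquivalentClasses, Inv, LogicId, Nominal,
                          Not, Some, SubClassOf, Top, Transitive,
                          check_profile)
from minidol.circumscription import CircumscriptionSpec
from minidol.dol import CircumscriptionLink, flatten
from minidol.fixtures import (GeneratorConfig, VARY_RECONCILIATION,
                              build_her2, build_mereology, random_ontology,
                              reconcile_vary)
from minidol.parser import parse_module
from minidol.printer import module_to_text
from minidol.reasoner import entails, find_model


class TestMereologyFixture:
    def test_module_and_link_counts(self, mereology):
        assert len(mereology.modules) == 6
        assert len(mereology.links) == 1

    def test_el_parthood_has_one_transitive_role(self, mereology):
        el = mereology.modules["ELParthood"]
        transitive = [ax for ax in el.axioms if isinstance(ax, Transitive)]
        assert len(transitive) == 1
        assert transitive[0].role == "isPartOf"

    def test_taxonomy_has_all_pairwise_disjointness(self, mereology):
        # six pairwise disjointness axioms for S, T, AR, PD + the union
        assert len(mereology.modules["Taxonomy"].axioms) == 7

    def test_atom_has_no_proper_parts(self, flat):
        goal = SubClassOf(Atomic("Atom"),
                          Not(Some(Inv("isProperPartOf"), Top())))
        assert entails(flat["ProperParthood"], goal, 3).holds

    def test_every_fixture_module_consistent_at_bound_4(self, mereology):
        for name in mereology.modules:
            assert find_model(flatten(mereology, name), 4) is not None

    def test_expdl_dirty_everyone_else_clean(self, flat):
        # OWL regularity only constrains the DL-family modules; the
        # first-order flattenings carry no role axioms to restrict
        for name, ont in flat.items():
            violations = check_profile(ont)
            if name == "Parthood":
                assert violations
            else:
                assert violations == []

    def test_classical_variant_differs_only_in_cl_axioms(self, mereology):
        classical = build_mereology("classical")
        for name in mereology.modules:
            a = mereology.modules[name].axioms
            b = classical.modules[name].axioms
            if name == "ClassicalExtensionalParthood":
                assert a != b
            else:
                assert a == b

    def test_classical_variant_consistent(self):
        classical = build_mereology("classical")
        cep = flatten(classical, "ClassicalExtensionalParthood")
        assert find_model(cep, 3) is not None


class TestHER2Fixture:
    def test_positive_class_is_the_3plus_nominal(self, her2_doc):
        mod = her2_doc.modules["HER2"]
        eq = {ax.left.name: ax.right for ax in mod.axioms
              if isinstance(ax, EquivalentClasses)
              and isinstance(ax.left, Atomic)
              and isinstance(ax.right, Nominal)}
        assert eq["HER2_Positive"] == Nominal(("3+",))
        assert eq["HER2_Negative"] == Nominal(("0", "1+"))

    def test_her2_subclass_of_proteins(self, her2_doc):
        mod = her2_doc.modules["HER2"]
        assert SubClassOf(Atomic("HER2"), Atomic("Proteins")) in mod.axioms

    def test_reconciled_vary_names_are_declared_classes(self, her2_doc):
        link = next(l for l in her2_doc.links
                    if isinstance(l, CircumscriptionLink))
        assert link.spec.varying == frozenset(
            {"Normal_Cell_Membrane", "Normal_Cell", "Normal_Tissue"})
        declared = her2_doc.modules["HER2"].signature.concepts
        assert link.spec.varying <= declared
        assert link.spec.minimised == frozenset(
            {"HER2+_Cell_Membrane", "HER2+_Cell", "HER2+_Tissue"})

    def test_printed_variant_keeps_undeclared_vary_names(self):
        printed = build_her2("as_printed")
        link = next(l for l in printed.links
                    if isinstance(l, CircumscriptionLink))
        assert "Normal_Cancer_Cell" in link.spec.varying
        # the parser records the auto-declaration
        assert "parser_warnings" in printed.modules["HER2"].annotations

    def test_reconciliation_table_maps_printed_to_declared(self):
        printed = build_her2("as_printed")
        reconciled = reconcile_vary(printed)
        link = next(l for l in reconciled.links
                    if isinstance(l, CircumscriptionLink))
        assert link.spec.varying == frozenset(VARY_RECONCILIATION.values())

    def test_both_variants_consistent_at_bound_6(self, her2):
        assert find_model(her2, 6) is not None
        printed = flatten(build_her2("as_printed"), "HER2")
        assert find_model(printed, 6) is not None


class TestRandomOntologies:
    def test_same_seed_same_module(self):
        a = random_ontology(GeneratorConfig(seed=11))
        b = random_ontology(GeneratorConfig(seed=11))
        assert a.axioms == b.axioms
        assert a.signature.concepts == b.signature.concepts

    def test_different_seeds_differ(self):
        a = random_ontology(GeneratorConfig(seed=1))
        b = random_ontology(GeneratorConfig(seed=2))
        assert a.axioms != b.axioms

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_generated_modules_parse_and_round_trip(self, seed):
        ont = random_ontology(GeneratorConfig(seed=seed, max_concepts=4,
                                              max_roles=2,
                                              max_individuals=3,
                                              n_axioms=10))
        back = parse_module(module_to_text(ont))
        assert set(map(repr, back.axioms)) == set(map(repr, ont.axioms))

    def test_signature_sizes_respect_config(self):
        cfg = GeneratorConfig(seed=3, max_concepts=4, max_roles=2,
                              max_individuals=3, n_axioms=10)
        ont = random_ontology(cfg)
        assert len(ont.signature.concepts) <= 4
        assert len(ont.signature.roles) <= 2
        assert len(ont.signature.individuals) <= 3
        assert ont.logic == LogicId.DL
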