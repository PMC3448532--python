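"""Dialect parsing: listings, errors, normalisation, round-trips."""

import pytest

from minidol.core import (Exactly, EquivalentClasses, Implies, LogicId,
                          Nominal, PropAxiom)
from minidol.errors import DialectSyntaxError, ExpressivityError
from minidol.fixtures import GeneratorConfig, fixture_text, random_ontology
from minidol.parser import parse_goal, parse_module
from minidol.printer import module_to_text


TAXONOMY = """
logic Propositional
ontology Taxonomy =
  props PT , PD , T , S , AR
  . S or T or AR or PD implies PT
  . S and T implies false
"""


class TestModuleParsing:
    def test_taxonomy_listing(self):
        ont = parse_module(TAXONOMY)
        assert ont.logic == LogicId.PROP
        assert ont.signature.props == {"PT", "PD", "T", "S", "AR"}
        implications = [ax for ax in ont.axioms
                        if isinstance(ax, PropAxiom)
                        and isinstance(ax.formula, Implies)]
        assert len(implications) >= 1

    def test_empty_module(self):
        ont = parse_module("logic DL ontology Empty =")
        assert ont.logic == LogicId.DL
        assert ont.axioms == []
        assert ont.name == "Empty"

    def test_her2_listing_cardinality_and_nominals(self):
        ont = parse_module(fixture_text("her2_reconciled")
                           .split("distributed-ontology HER2")[1])
        assert ont.logic == LogicId.DL
        exact = [n for ax in ont.axioms for n in _walk(ax)
                 if isinstance(n, Exactly)]
        assert any(n.n == 1 and n.role == "hasHER2Score" for n in exact)
        nominal_classes = {
            ax.right.individuals for ax in ont.axioms
            if isinstance(ax, EquivalentClasses)
            and isinstance(ax.right, Nominal)}
        assert ("0", "1+") in nominal_classes
        assert ("2+",) in nominal_classes
        assert ("3+",) in nominal_classes

    def test_unicode_connectives_accepted(self):
        ont = parse_module("logic Propositional ontology U =\n"
                           "props A B\n. A ⋀ B → ⊥")
        (ax,) = ont.axioms
        assert isinstance(ax.formula, Implies)

    def test_plus_and_dash_inside_identifiers(self):
        ont = parse_module("logic DL ontology P =\n"
                           "Class HER2+_Cell SubClassOf Normal-ish")
        assert "HER2+_Cell" in ont.signature.concepts
        assert "Normal-ish" in ont.signature.concepts


class TestErrors:
    def test_syntax_error_carries_position(self):
        with pytest.raises(DialectSyntaxError) as err:
            parse_module("logic DL\nontology Bad =\nClass SubClassOf A")
        assert err.value.line == 3

    def test_asymmetric_forbidden_in_el(self):
        with pytest.raises(ExpressivityError) as err:
            parse_module("logic EL ontology E =\n"
                         "ObjectProperty r Characteristics Asymmetric")
        assert "Asymmetric" in str(err.value)

    @pytest.mark.parametrize("concept", ["( Not A )", "( A Or B )",
                                         "( r Only A )",
                                         "( r Exactly 1 A )"])
    def test_el_forbids_boolean_and_cardinality_constructs(self, concept):
        with pytest.raises(ExpressivityError):
            parse_module(f"logic EL ontology E =\nClass C SubClassOf "
                         f"{concept}")

    def test_two_logic_blocks_rejected_by_parse_module(self):
        with pytest.raises(DialectSyntaxError):
            parse_module("distributed-ontology D\nlogic DL ontology A =")


class TestNormalisation:
    def test_case_drift_normalised_with_warning(self):
        ont = parse_module("logic DL ontology N =\n"
                          "ObjectProperty isPartOf Characteristics Transitive\n"
                          "ObjectProperty ispartof SubPropertyOf isPartOf")
        assert "ispartof" not in ont.signature.roles
        assert "isPartOf" in ont.signature.roles
        assert "parser_warnings" in ont.annotations


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(25))
    def test_print_parse_round_trip(self, seed):
        """parse(print(O)) equals O up to axiom order."""
        ont = random_ontology(GeneratorConfig(seed=seed))
        back = parse_module(module_to_text(ont))
        assert back.name == ont.name
        assert back.logic == ont.logic
        assert back.signature.concepts == ont.signature.concepts
        assert back.signature.roles == ont.signature.roles
        assert back.signature.individuals == ont.signature.individuals
        assert set(map(repr, back.axioms)) == set(map(repr, ont.axioms))

    def test_fixture_documents_round_trip(self, mereology):
        for name, mod in mereology.modules.items():
            back = parse_module(module_to_text(mod))
            assert set(map(repr, back.axioms)) == set(map(repr, mod.axioms))
            assert back.logic == mod.logic


def test_parse_goal_individual_frame(her2):
    goal = parse_goal("Individual X Types HER2+_Tissue", her2.logic,
                      her2.signature)
    from minidol.core import ClassAssertion
    assert isinstance(goal, ClassAssertion)
    assert goal.individual == "X"


def _walk(node):
    yield node
    for attr in ("arg", "sub", "sup", "left", "right", "filler", "formula",
                 "concept", "body"):
        ch = getattr(node, attr, None)
        if ch is not None and not isinstance(ch, (str, int, tuple)):
            yield from _walk(ch)
    for attr in ("args", "parts"):
        chs = getattr(node, attr, None)
        if isinstance(chs, tuple):
            for ch in chs:
                if not isinstance(ch, (str, int)):
                    yield from _walk(ch)
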