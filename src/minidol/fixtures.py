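"""Executable encodings of the two case studies, plus a random generator.

* :func:`build_mereology` — the six-module mereology tower (propositional
  taxonomy, EL parthood, OWL proper parthood, an expressivity-exceeding
  DL module, first-order overlap, and the Common Logic module with
  second-order category guards, sum and fusion) together with the
  ``TaxonomyToELParthood`` interpretation link.  The printed sum/fusion
  definitions use a conjunctive overlap condition where classical
  extensional mereology uses a disjunctive one; both variants ship
  (``as_printed`` and ``classical``) and neither is asserted to be
  canonical.
* :func:`build_her2` — the HER2 breast-phenotype ontology extending
  ProperParthood: IHC scores 0/1+/2+/3+ as nominals (the >30% staining
  threshold is qualitatively abstracted into score classes), disjoint
  normal/HER2+ partitions of Cell and Tissue, the measured individual X
  (score 3+) and the unmeasured individual Y, and the circumscription
  block minimising the HER2+ ("abnormal") concepts.  The printed vary
  list names Normal_Cancer_* classes that are never declared; the
  ``reconciled`` variant maps them to the declared Normal_* classes, the
  ``as_printed`` variant keeps them verbatim.
* :func:`random_ontology` — a seeded generator of small description-logic
  modules for property tests (engine equivalence, round-trips).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from .core import (And, Atomic, Bottom, ClassAssertion,
                   DifferentFrom, DisjointClasses, LogicId, Not, Ontology,
                   Or, RoleAssertion, Signature, Some, SubClassOf,
                   SubPropertyOf, Top, Transitive)
from .circumscription import CircumscriptionSpec
from .dol import CircumscriptionLink, DistributedOntology, parse_distributed

__all__ = ["build_mereology", "build_her2", "GeneratorConfig",
           "random_ontology", "fixture_text", "fixture_names",
           "reconcile_vary", "VARY_RECONCILIATION"]

_FIXTURES = {
    "mereology": "mereology.mdol",
    "mereology_classical": "mereology_classical.mdol",
    "her2_reconciled": "her2_reconciled.mdol",
    "her2_printed": "her2_printed.mdol",
}

# printed vary names -> declared classes (user-overridable)
VARY_RECONCILIATION = {
    "Normal_Cancer_Cell_Membrane": "Normal_Cell_Membrane",
    "Normal_Cancer_Cell": "Normal_Cell",
    "Normal_Cancer-Tissue": "Normal_Tissue",
}


def fixture_names() -> list:
    return sorted(_FIXTURES)


def fixture_text(name: str) -> str:
    """Raw ``.mdol`` source of a named fixture."""
    fname = _FIXTURES[name]
    return (resources.files("minidol.fixtures_data") / fname).read_text(
        encoding="utf-8")


def build_mereology(variant: str = "as_printed") -> DistributedOntology:
    """The mereology document: six modules and one interpretation link."""
    key = "mereology" if variant == "as_printed" else "mereology_classical"
    return parse_distributed(fixture_text(key))


def build_her2(variant: str = "reconciled",
               vary_map: dict = None) -> DistributedOntology:
    """The HER2 document (one module + circumscription block).

    The module imports ProperParthood, resolved against the mereology
    document, which is attached as the parse context.  For the
    ``as_printed`` variant, ``vary_map`` (default
    :data:`VARY_RECONCILIATION`) may be applied afterwards with
    :func:`reconcile_vary`.
    """
    key = "her2_reconciled" if variant == "reconciled" else "her2_printed"
    mereology = build_mereology()
    return parse_distributed(fixture_text(key), context=mereology)


def reconcile_vary(doc: DistributedOntology,
                   vary_map: dict = None) -> DistributedOntology:
    """Rewrite circumscription vary lists through a name mapping table."""
    vary_map = VARY_RECONCILIATION if vary_map is None else vary_map
    for link in doc.links:
        if isinstance(link, CircumscriptionLink):
            link.spec = CircumscriptionSpec(
                link.spec.minimised,
                frozenset(vary_map.get(n, n) for n in link.spec.varying))
    return doc


# ---------------------------------------------------------------------------
# seeded random ontologies (DL fragment)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Signature/axiom budget for :func:`random_ontology`."""

    seed: int = 0
    max_concepts: int = 4
    max_roles: int = 2
    max_individuals: int = 3
    n_axioms: int = 10


def _random_concept(rng: random.Random, concepts, roles, depth: int):
    if depth <= 0 or not roles or rng.random() < 0.55:
        r = rng.random()
        if r < 0.85 or not concepts:
            if concepts and r >= 0.08:
                return Atomic(rng.choice(concepts))
            return Top() if rng.random() < 0.5 else Bottom()
        return Atomic(rng.choice(concepts))
    kind = rng.choice(["not", "and", "or", "some"])
    if kind == "not":
        return Not(_random_concept(rng, concepts, roles, depth - 1))
    if kind == "some":
        return Some(rng.choice(roles),
                    _random_concept(rng, concepts, roles, depth - 1))
    parts = tuple(_random_concept(rng, concepts, roles, depth - 1)
                  for _ in range(2))
    return And(parts) if kind == "and" else Or(parts)


def random_ontology(config: GeneratorConfig) -> Ontology:
    """A deterministic random DL module (same seed, same module)."""
    rng = random.Random(config.seed)
    n_c = rng.randint(1, config.max_concepts)
    n_r = rng.randint(0, config.max_roles)
    n_i = rng.randint(0, config.max_individuals)
    concepts = [f"C{i}" for i in range(n_c)]
    roles = [f"r{i}" for i in range(n_r)]
    individuals = [f"a{i}" for i in range(n_i)]
    sig = Signature(concepts=set(concepts), roles=set(roles),
                    individuals=set(individuals))
    axioms = []
    for _ in range(config.n_axioms):
        kinds = ["sub", "sub", "sub", "disjoint"]
        if roles:
            kinds += ["transitive", "subrole"]
        if individuals:
            kinds += ["assert", "assert"]
            if roles:
                kinds.append("fact")
        if len(individuals) >= 2:
            kinds.append("different")
        kind = rng.choice(kinds)
        if kind == "sub":
            axioms.append(SubClassOf(
                _random_concept(rng, concepts, roles, 2),
                _random_concept(rng, concepts, roles, 2)))
        elif kind == "disjoint" and len(concepts) >= 2:
            a, b = rng.sample(concepts, 2)
            axioms.append(DisjointClasses((Atomic(a), Atomic(b))))
        elif kind == "transitive":
            axioms.append(Transitive(rng.choice(roles)))
        elif kind == "subrole" and len(roles) >= 1:
            axioms.append(SubPropertyOf(rng.choice(roles),
                                        rng.choice(roles)))
        elif kind == "assert":
            axioms.append(ClassAssertion(
                _random_concept(rng, concepts, roles, 1),
                rng.choice(individuals)))
        elif kind == "fact":
            axioms.append(RoleAssertion(rng.choice(roles),
                                        rng.choice(individuals),
                                        rng.choice(individuals)))
        elif kind == "different":
            a, b = rng.sample(individuals, 2)
            axioms.append(DifferentFrom(a, b))
    return Ontology(name=f"Random{config.seed}", logic=LogicId.DL,
                    signature=sig, axioms=axioms)
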