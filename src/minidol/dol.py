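"""The distributed-ontology layer: multi-module documents and links.

A document holds named modules, possibly written in different logics, plus
link records: ``interpretation`` links (theory-morphism requirements,
verified by translation and bounded entailment), circumscription blocks
(``minimise`` / ``vary`` with ``%implies`` obligations), and the
``combine`` operation for alignment-driven merging.  Modules import one
another with ``then``; flattening resolves the import closure, translating
everything into the least expressive logic of the tower that admits all
imported content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import networkx as nx

from .circumscription import CircumscriptionSpec, circ_entails
from .core import (And, Asymmetric, Atomic, ClassAssertion, Const,
                   DifferentFrom, DisjointClasses, DisjointUnion, Eq,
                   EquivalentClasses, Exactly, ExistsI, ExistsP, ExtEq, FAnd,
                   FIff, FImplies, FNot, FOr, ForallI, ForallP, Implies, Inv,
                   Nominal, Not, Only, Ontology, Or, PredAtom,
                   PropAxiom, RoleAssertion, Signature, Some, SubClassOf,
                   SubPropertyChain, SubPropertyOf, Top, Transitive, Var)
from .errors import CombineError, LinkError
from .parser import parse_document_items
from .reasoner import BoundedVerdict, entails, find_model
from .translations import EDGES, check_interpretation, translate_axiom, \
    translate_signature

__all__ = ["DistributedOntology", "InterpretationLink", "CircumscriptionLink",
           "AlignmentCorrespondence", "parse_distributed", "flatten",
           "combine", "verify_document", "ReportItem", "DocumentReport",
           "load_alignment"]


@dataclass
class InterpretationLink:
    name: str
    source: str
    target: str
    edge: Optional[str] = None


@dataclass
class CircumscriptionLink:
    base: str
    spec: CircumscriptionSpec
    implied: list = field(default_factory=list)


@dataclass
class DistributedOntology:
    """A named document: modules plus links between them.

    ``context`` optionally names another document whose modules are
    visible for import resolution (module reuse across documents, e.g. a
    phenotype document importing a mereology tower).
    """

    name: Optional[str]
    modules: dict = field(default_factory=dict)
    links: list = field(default_factory=list)
    context: Optional["DistributedOntology"] = None

    def has_module(self, name: str) -> bool:
        return name in self.modules or (
            self.context is not None and self.context.has_module(name))

    def module(self, name: str) -> Ontology:
        if name in self.modules:
            return self.modules[name]
        if self.context is not None and self.context.has_module(name):
            return self.context.module(name)
        raise LinkError(f"unknown module {name!r}")


def parse_distributed(text: str,
                      context: Optional[DistributedOntology] = None) \
        -> DistributedOntology:
    """Parse a distributed-ontology document.

    All modules share one identifier normaliser, so casing drift between
    modules resolves to a single canonical spelling.  Dangling imports and
    link references (not resolvable in the document or its ``context``)
    raise :class:`~minidol.errors.LinkError`.
    """
    items = parse_document_items(text)
    doc = DistributedOntology(name=None, context=context)
    for item in items:
        if item[0] == "document":
            doc.name = item[1]
        elif item[0] == "module":
            _, ont, circ = item
            doc.modules[ont.name] = ont
            if circ is not None:
                doc.links.append(CircumscriptionLink(
                    base=ont.name,
                    spec=CircumscriptionSpec(frozenset(circ.minimised),
                                             frozenset(circ.varying)),
                    implied=list(circ.implied)))
        elif item[0] == "interpretation":
            _, name, src, edge, tgt = item
            doc.links.append(InterpretationLink(name, src, tgt, edge))
    _validate(doc)
    return doc


def _validate(doc: DistributedOntology) -> None:
    g = nx.DiGraph()
    for name, ont in doc.modules.items():
        g.add_node(name)
        for imp, _edge in ont.imports:
            if not doc.has_module(imp):
                raise LinkError(
                    f"module {name!r} imports unknown module {imp!r}")
            g.add_edge(name, imp)
    if doc.context is not None:
        for name, ont in doc.context.modules.items():
            for imp, _edge in ont.imports:
                g.add_edge(name, imp)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise LinkError(f"import cycle: {cycle}")
    for link in doc.links:
        if isinstance(link, InterpretationLink):
            for ref in (link.source, link.target):
                if not doc.has_module(ref):
                    raise LinkError(
                        f"interpretation {link.name!r} references unknown "
                        f"module {ref!r}")
        elif isinstance(link, CircumscriptionLink):
            if link.base not in doc.modules:
                raise LinkError(f"circumscription block references unknown "
                                f"module {link.base!r}")


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------

def _closure(doc: DistributedOntology, name: str) -> list:
    """Deterministic import closure, imports before importers."""
    out, seen = [], set()

    def visit(n: str):
        if n in seen:
            return
        seen.add(n)
        ont = doc.module(n)
        for imp, _edge in sorted(ont.imports):
            visit(imp)
        out.append(n)

    visit(name)
    return out


def flatten(doc: DistributedOntology, name: str) -> Ontology:
    """Resolve the ``then`` import closure of one module.

    The result lives in the least expressive logic of the tower that
    admits all imported content (the maximum along the closure, since
    imports come from below); each module's axioms and signature are
    translated along the graph.  Flattening a module with no imports
    returns an equal ontology, so the operation is idempotent.
    """
    order = _closure(doc, name)
    target = max(doc.module(n).logic for n in order)
    sig = Signature()
    axioms: list = []
    for n in order:
        mod = doc.module(n)
        sig = sig.union(translate_signature(mod.signature, mod.logic,
                                            target))
        axioms.extend(translate_axiom(ax, mod.logic, target)
                      for ax in mod.axioms)
    out = Ontology(name=name, logic=target, signature=sig, axioms=axioms)
    out.annotations = dict(doc.module(name).annotations)
    out.circ_block = getattr(doc.module(name), "circ_block", None)
    return out


# ---------------------------------------------------------------------------
# combine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentCorrespondence:
    """A correspondence 〈source term, target term, relation, confidence〉.

    ``relation`` is ``synonym`` (strict identification), ``subsumes``
    (source below target) or ``part_of``.  The confidence value is
    recorded as an annotation only; it never affects semantics.
    """

    source_term: str
    target_term: str
    relation: str = "synonym"
    confidence: float = 1.0

    def __post_init__(self):
        if self.relation not in ("synonym", "subsumes", "part_of"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


def load_alignment(path) -> list:
    """Read a tab-delimited alignment file (source, target, relation,
    confidence)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            src, tgt = parts[0], parts[1]
            rel = parts[2] if len(parts) > 2 else "synonym"
            conf = float(parts[3]) if len(parts) > 3 else 1.0
            out.append(AlignmentCorrespondence(src, tgt, rel, conf))
    return out


def _category(sig: Signature, name: str) -> Optional[str]:
    if name in sig.concepts:
        return "concept"
    if name in sig.roles:
        return "role"
    if name in sig.individuals:
        return "individual"
    if name in sig.props:
        return "prop"
    if any(n == name for n, _ in sig.predicates):
        return "predicate"
    return None


def _rename(node, mapping: dict):
    """Rename signature symbols throughout a formula."""
    def m(n):
        return mapping.get(n, n)

    if isinstance(node, Atomic):
        return Atomic(m(node.name))
    if isinstance(node, (Top, type(None))) or node is None:
        return node
    if isinstance(node, Nominal):
        return Nominal(tuple(m(i) for i in node.individuals))
    if isinstance(node, Inv):
        return Inv(m(node.role))
    if isinstance(node, (Some, Only)):
        role = Inv(m(node.role.role)) if isinstance(node.role, Inv) \
            else m(node.role)
        return type(node)(role, _rename(node.filler, mapping))
    if isinstance(node, Exactly):
        role = Inv(m(node.role.role)) if isinstance(node.role, Inv) \
            else m(node.role)
        return Exactly(node.n, role, _rename(node.filler, mapping))
    if isinstance(node, Not):
        return Not(_rename(node.arg, mapping))
    if isinstance(node, (And, Or)):
        return type(node)(tuple(_rename(a, mapping) for a in node.args))
    if isinstance(node, Implies):
        return Implies(_rename(node.left, mapping),
                       _rename(node.right, mapping))
    if isinstance(node, SubClassOf):
        return SubClassOf(_rename(node.sub, mapping),
                          _rename(node.sup, mapping))
    if isinstance(node, EquivalentClasses):
        return EquivalentClasses(_rename(node.left, mapping),
                                 _rename(node.right, mapping))
    if isinstance(node, DisjointUnion):
        return DisjointUnion(m(node.name),
                             tuple(_rename(p, mapping) for p in node.parts))
    if isinstance(node, DisjointClasses):
        return DisjointClasses(tuple(_rename(p, mapping)
                                     for p in node.parts))
    if isinstance(node, Transitive):
        return Transitive(m(node.role))
    if isinstance(node, Asymmetric):
        return Asymmetric(m(node.role))
    if isinstance(node, SubPropertyOf):
        return SubPropertyOf(m(node.sub), m(node.sup))
    if isinstance(node, SubPropertyChain):
        return SubPropertyChain(tuple(m(r) for r in node.chain), m(node.sup))
    if isinstance(node, ClassAssertion):
        return ClassAssertion(_rename(node.concept, mapping),
                              m(node.individual))
    if isinstance(node, RoleAssertion):
        return RoleAssertion(m(node.role), m(node.subject), m(node.object))
    if isinstance(node, DifferentFrom):
        return DifferentFrom(m(node.a), m(node.b))
    if isinstance(node, PropAxiom):
        return PropAxiom(_rename(node.formula, mapping))
    if isinstance(node, Const):
        return Const(m(node.name))
    if isinstance(node, Var):
        return node
    if isinstance(node, PredAtom):
        pred = node.pred if isinstance(node.pred, Var) else m(node.pred)
        return PredAtom(pred, tuple(_rename(a, mapping) for a in node.args))
    if isinstance(node, Eq):
        return Eq(_rename(node.left, mapping), _rename(node.right, mapping))
    if isinstance(node, ExtEq):
        return ExtEq(node.var, m(node.pred))
    if isinstance(node, (FNot,)):
        return FNot(_rename(node.arg, mapping))
    if isinstance(node, (FAnd, FOr)):
        return type(node)(tuple(_rename(a, mapping) for a in node.args))
    if isinstance(node, (FImplies, FIff)):
        return type(node)(_rename(node.left, mapping),
                          _rename(node.right, mapping))
    if isinstance(node, (ForallI, ExistsI, ForallP, ExistsP)):
        return type(node)(node.vars, _rename(node.body, mapping))
    return node


def combine(inputs: Iterable[Ontology],
            alignment: Iterable[AlignmentCorrespondence] = ()) -> Ontology:
    """Merge ontologies while respecting alignment identifications.

    ``synonym`` correspondences identify the two terms (the target term is
    renamed to the source term everywhere); ``subsumes`` adds
    ``source [= target``; ``part_of`` adds ``source [= isPartOf some
    target``.  Confidence values are stored as annotations and never
    influence any verdict.  An identification across different signature
    categories raises :class:`~minidol.errors.CombineError`.
    """
    inputs = [o for o in inputs]
    if not inputs:
        raise CombineError("combine requires at least one ontology")
    alignment = list(alignment)
    target_logic = max(o.logic for o in inputs)

    mapping: dict = {}
    for corr in alignment:
        if corr.relation == "synonym":
            src = mapping.get(corr.source_term, corr.source_term)
            mapping[corr.target_term] = src

    # category clash detection (after renaming)
    cats: dict = {}
    for ont in inputs:
        for cat_name, names in (("concept", ont.signature.concepts),
                                ("role", ont.signature.roles),
                                ("individual", ont.signature.individuals),
                                ("prop", ont.signature.props)):
            for n in names:
                canon = mapping.get(n, n)
                if canon in cats and cats[canon] != cat_name:
                    raise CombineError(
                        f"identification maps {n!r} into category "
                        f"{cat_name}, clashing with {cats[canon]}")
                cats[canon] = cat_name

    from .translations import translate
    sig = Signature()
    axioms: list = []
    for ont in inputs:
        ont_t = translate(ont, target_logic)
        renamed_sig = Signature(
            concepts={mapping.get(n, n) for n in ont_t.signature.concepts},
            roles={mapping.get(n, n) for n in ont_t.signature.roles},
            individuals={mapping.get(n, n)
                         for n in ont_t.signature.individuals},
            props={mapping.get(n, n) for n in ont_t.signature.props},
            predicates={(mapping.get(n, n), a)
                        for n, a in ont_t.signature.predicates},
        )
        sig = sig.union(renamed_sig)
        axioms.extend(_rename(ax, mapping) for ax in ont_t.axioms)

    for corr in alignment:
        s = mapping.get(corr.source_term, corr.source_term)
        t = mapping.get(corr.target_term, corr.target_term)
        if corr.relation == "subsumes":
            axioms.append(SubClassOf(Atomic(s), Atomic(t)))
            sig.concepts |= {s, t}
        elif corr.relation == "part_of":
            sig.roles.add("isPartOf")
            axioms.append(SubClassOf(Atomic(s),
                                     Some("isPartOf", Atomic(t))))
            sig.concepts |= {s, t}
    sig.validate()

    out = Ontology(name="+".join(o.name for o in inputs),
                   logic=target_logic, signature=sig, axioms=axioms)
    for i, corr in enumerate(alignment):
        out.annotations[f"alignment_{i}"] = (
            f"{corr.source_term} {corr.relation} {corr.target_term} "
            f"confidence={corr.confidence}")
    return out


# ---------------------------------------------------------------------------
# document verification
# ---------------------------------------------------------------------------

@dataclass
class ReportItem:
    kind: str        # "consistency" | "interpretation" | "implies"
    name: str
    passed: bool
    detail: str = ""
    verdict: Optional[BoundedVerdict] = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "name": self.name, "passed": self.passed,
                "detail": self.detail}


@dataclass
class DocumentReport:
    bound: int
    items: List[ReportItem] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(item.passed for item in self.items)

    def to_dict(self) -> dict:
        return {"bound": self.bound, "passed": self.passed,
                "items": [i.to_dict() for i in self.items]}


def verify_document(doc: DistributedOntology, bound: int,
                    engine: str = "ground") -> DocumentReport:
    """Check every module's consistency, every interpretation link, and
    every ``%implies`` obligation (circumscriptively inside a
    circumscription block, classically otherwise)."""
    report = DocumentReport(bound=bound)
    flats = {name: flatten(doc, name) for name in sorted(doc.modules)}

    for name, flat in flats.items():
        model = find_model(flat, bound, engine=engine)
        report.items.append(ReportItem(
            "consistency", name, model is not None,
            "consistent within bound" if model is not None
            else "no model within bound"))

    for link in doc.links:
        if isinstance(link, InterpretationLink):
            edge = EDGES.get(link.edge) if link.edge else None
            verdict = check_interpretation(flats[link.source],
                                           flats[link.target],
                                           edge=edge, bound=bound,
                                           engine=engine)
            report.items.append(ReportItem(
                "interpretation", link.name, verdict.holds,
                verdict.status, verdict))
        elif isinstance(link, CircumscriptionLink):
            base = flats[link.base]
            for i, goal in enumerate(link.implied):
                if link.spec.is_classical:
                    verdict = entails(base, goal, bound, engine=engine)
                else:
                    verdict = circ_entails(base, link.spec, goal, bound,
                                           engine=engine)
                report.items.append(ReportItem(
                    "implies", f"{link.base}#implies{i}", verdict.holds,
                    verdict.status, verdict))
    return report
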