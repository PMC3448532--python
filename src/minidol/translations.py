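"""The logic translation graph and sentence-level translations.

Edges follow the linear tower PROP -> DL, EL -> DL, DL -> EXPDL,
EXPDL -> FOL, FOL -> CL.  The propositional translation renders an
implication as a concept subsumption (valuations correspond to per-element
membership patterns); the description-logic translation into first-order
logic is the standard relational one (concepts to unary predicates,
restrictions to guarded quantification, role characteristics to their
first-order axioms).  Compositions are available wherever a directed path
exists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional

import networkx as nx

from .core import (And, Asymmetric, Atomic, Bottom, ClassAssertion, Const,
                   DifferentFrom, DisjointClasses, DisjointUnion, Eq,
                   EquivalentClasses, Exactly, ExistsI, FAnd, FIff, FImplies,
                   FNot, FOr, ForallI, Implies, Inv, LogicId, Nominal, Not,
                   Only, Ontology, Or, PredAtom, PropAxiom, RoleAssertion,
                   Signature, Some, SubClassOf, SubPropertyChain,
                   SubPropertyOf, Top, Transitive, Var)
from .errors import UntranslatableError

__all__ = ["TranslationEdge", "EDGES", "translation_graph", "translate",
           "translate_axiom", "translate_signature", "prop_to_dl_axiom",
           "dl_to_fol_axiom", "common_supralogic"]


@dataclass
class TranslationEdge:
    """A satisfaction-preserving sentence-and-symbol map between two logics."""

    name: str
    source: LogicId
    target: LogicId
    sentence_map: Callable
    signature_map: Callable


# ---------------------------------------------------------------------------
# Prop -> DL
# ---------------------------------------------------------------------------

def _prop_concept(f):
    """Propositional formula over symbols -> concept over the same names."""
    if isinstance(f, Atomic):
        return Atomic(f.name)
    if isinstance(f, (Top, Bottom)):
        return f
    if isinstance(f, Not):
        return Not(_prop_concept(f.arg))
    if isinstance(f, And):
        return And(tuple(_prop_concept(a) for a in f.args))
    if isinstance(f, Or):
        return Or(tuple(_prop_concept(a) for a in f.args))
    if isinstance(f, Implies):
        return Or((Not(_prop_concept(f.left)), _prop_concept(f.right)))
    raise TypeError(f"not a propositional formula: {f!r}")


def prop_to_dl_axiom(ax):
    """Implication phi -> psi becomes tau(phi) [= tau(psi); a bare formula
    phi becomes Thing [= tau(phi)."""
    if not isinstance(ax, PropAxiom):
        raise TypeError(f"expected a propositional axiom, got {ax!r}")
    f = ax.formula
    if isinstance(f, Implies):
        return SubClassOf(_prop_concept(f.left), _prop_concept(f.right))
    return SubClassOf(Top(), _prop_concept(f))


def _prop_to_dl_signature(sig: Signature) -> Signature:
    out = sig.copy()
    out.concepts |= out.props
    out.props = set()
    return out


# ---------------------------------------------------------------------------
# DL -> FOL (standard relational translation)
# ---------------------------------------------------------------------------

class _VarGen:
    def __init__(self):
        self.i = 0

    def __call__(self) -> str:
        self.i += 1
        return f"x{self.i}"


def _role_atom(role, s, o):
    if isinstance(role, Inv):
        return PredAtom(role.role, (o, s))
    return PredAtom(role, (s, o))


def _concept_fol(c, x: str, gen: _VarGen):
    """First-order rendering of concept ``c`` with free variable ``x``."""
    v = Var(x)
    if isinstance(c, Top):
        return FAnd(())
    if isinstance(c, Bottom):
        return FOr(())
    if isinstance(c, Atomic):
        return PredAtom(c.name, (v,))
    if isinstance(c, Not):
        return FNot(_concept_fol(c.arg, x, gen))
    if isinstance(c, And):
        return FAnd(tuple(_concept_fol(a, x, gen) for a in c.args))
    if isinstance(c, Or):
        return FOr(tuple(_concept_fol(a, x, gen) for a in c.args))
    if isinstance(c, Implies):
        return FImplies(_concept_fol(c.left, x, gen),
                        _concept_fol(c.right, x, gen))
    if isinstance(c, Some):
        y = gen()
        return ExistsI((y,), FAnd((_role_atom(c.role, v, Var(y)),
                                   _concept_fol(c.filler, y, gen))))
    if isinstance(c, Only):
        y = gen()
        return ForallI((y,), FImplies(_role_atom(c.role, v, Var(y)),
                                      _concept_fol(c.filler, y, gen)))
    if isinstance(c, Exactly):
        k = c.n
        # at least k
        parts = []
        if k > 0:
            ys = [gen() for _ in range(k)]
            conj = [_role_atom(c.role, v, Var(y)) for y in ys]
            conj += [_concept_fol(c.filler, y, gen) for y in ys]
            conj += [FNot(Eq(Var(a), Var(b)))
                     for a, b in itertools.combinations(ys, 2)]
            parts.append(ExistsI(tuple(ys), FAnd(tuple(conj))))
        # at most k
        ys = [gen() for _ in range(k + 1)]
        conj = [_role_atom(c.role, v, Var(y)) for y in ys]
        conj += [_concept_fol(c.filler, y, gen) for y in ys]
        disj = [Eq(Var(a), Var(b))
                for a, b in itertools.combinations(ys, 2)]
        parts.append(ForallI(tuple(ys),
                             FImplies(FAnd(tuple(conj)), FOr(tuple(disj)))))
        return FAnd(tuple(parts))
    if isinstance(c, Nominal):
        return FOr(tuple(Eq(v, Const(i)) for i in c.individuals))
    raise TypeError(f"not a concept: {c!r}")


def _subst_var(f, var: str, const: Const):
    """Substitute ``Const`` for the free variable ``var`` in a formula."""
    if isinstance(f, Var):
        return const if f.name == var else f
    if isinstance(f, Const):
        return f
    if isinstance(f, PredAtom):
        return PredAtom(f.pred, tuple(_subst_var(a, var, const)
                                      for a in f.args))
    if isinstance(f, Eq):
        return Eq(_subst_var(f.left, var, const),
                  _subst_var(f.right, var, const))
    if isinstance(f, FNot):
        return FNot(_subst_var(f.arg, var, const))
    if isinstance(f, FAnd):
        return FAnd(tuple(_subst_var(a, var, const) for a in f.args))
    if isinstance(f, FOr):
        return FOr(tuple(_subst_var(a, var, const) for a in f.args))
    if isinstance(f, FImplies):
        return FImplies(_subst_var(f.left, var, const),
                        _subst_var(f.right, var, const))
    if isinstance(f, FIff):
        return FIff(_subst_var(f.left, var, const),
                    _subst_var(f.right, var, const))
    if isinstance(f, (ForallI, ExistsI)):
        if var in f.vars:
            return f
        return type(f)(f.vars, _subst_var(f.body, var, const))
    return f


def dl_to_fol_axiom(ax):
    gen = _VarGen()
    x, y, z = "x", "y", "z"

    def fa(vars_, body):
        return ForallI(tuple(vars_), body)

    if isinstance(ax, SubClassOf):
        return fa([x], FImplies(_concept_fol(ax.sub, x, gen),
                                _concept_fol(ax.sup, x, gen)))
    if isinstance(ax, EquivalentClasses):
        return fa([x], FIff(_concept_fol(ax.left, x, gen),
                            _concept_fol(ax.right, x, gen)))
    if isinstance(ax, DisjointUnion):
        parts = list(ax.parts)
        eq = fa([x], FIff(PredAtom(ax.name, (Var(x),)),
                          FOr(tuple(_concept_fol(p, x, gen) for p in parts))))
        disj = [fa([x], FNot(FAnd((_concept_fol(a, x, gen),
                                   _concept_fol(b, x, gen)))))
                for a, b in itertools.combinations(parts, 2)]
        return FAnd(tuple([eq] + disj))
    if isinstance(ax, DisjointClasses):
        disj = [fa([x], FNot(FAnd((_concept_fol(a, x, gen),
                                   _concept_fol(b, x, gen)))))
                for a, b in itertools.combinations(ax.parts, 2)]
        return FAnd(tuple(disj))
    if isinstance(ax, Transitive):
        r = ax.role
        return fa([x, y, z], FImplies(
            FAnd((PredAtom(r, (Var(x), Var(y))),
                  PredAtom(r, (Var(y), Var(z))))),
            PredAtom(r, (Var(x), Var(z)))))
    if isinstance(ax, Asymmetric):
        r = ax.role
        return fa([x, y], FImplies(PredAtom(r, (Var(x), Var(y))),
                                   FNot(PredAtom(r, (Var(y), Var(x))))))
    if isinstance(ax, SubPropertyOf):
        return fa([x, y], FImplies(PredAtom(ax.sub, (Var(x), Var(y))),
                                   PredAtom(ax.sup, (Var(x), Var(y)))))
    if isinstance(ax, SubPropertyChain):
        vars_ = [f"x{i}" for i in range(len(ax.chain) + 1)]
        conj = [PredAtom(r, (Var(vars_[i]), Var(vars_[i + 1])))
                for i, r in enumerate(ax.chain)]
        return fa(vars_, FImplies(FAnd(tuple(conj)),
                                  PredAtom(ax.sup, (Var(vars_[0]),
                                                    Var(vars_[-1])))))
    if isinstance(ax, ClassAssertion):
        body = _concept_fol(ax.concept, x, gen)
        return _subst_var(body, x, Const(ax.individual))
    if isinstance(ax, RoleAssertion):
        return PredAtom(ax.role, (Const(ax.subject), Const(ax.object)))
    if isinstance(ax, DifferentFrom):
        return FNot(Eq(Const(ax.a), Const(ax.b)))
    # first-order axioms pass through unchanged (EXPDL -> FOL on mixed content)
    return ax


def _dl_to_fol_signature(sig: Signature) -> Signature:
    out = Signature(individuals=set(sig.individuals),
                    predicates=set(sig.predicates))
    out.predicates |= {(c, 1) for c in sig.concepts}
    out.predicates |= {(r, 2) for r in sig.roles}
    return out


def _identity_axiom(ax):
    return ax


def _identity_signature(sig: Signature) -> Signature:
    return sig.copy()


# ---------------------------------------------------------------------------
# The graph
# ---------------------------------------------------------------------------

EDGES = {
    "PropToOWL": TranslationEdge("PropToOWL", LogicId.PROP, LogicId.DL,
                                 prop_to_dl_axiom, _prop_to_dl_signature),
    "ELToOWL": TranslationEdge("ELToOWL", LogicId.EL, LogicId.DL,
                               _identity_axiom, _identity_signature),
    "OWLToExpDL": TranslationEdge("OWLToExpDL", LogicId.DL, LogicId.EXPDL,
                                  _identity_axiom, _identity_signature),
    "ExpDLToFOL": TranslationEdge("ExpDLToFOL", LogicId.EXPDL, LogicId.FOL,
                                  dl_to_fol_axiom, _dl_to_fol_signature),
    "FOLToCL": TranslationEdge("FOLToCL", LogicId.FOL, LogicId.CL,
                               _identity_axiom, _identity_signature),
}


def translation_graph() -> nx.DiGraph:
    g = nx.DiGraph()
    for logic in LogicId:
        g.add_node(logic)
    for edge in EDGES.values():
        g.add_edge(edge.source, edge.target, edge=edge)
    return g


_GRAPH = translation_graph()


def _edge_path(source: LogicId, target: LogicId) -> list:
    if source == target:
        return []
    try:
        nodes = nx.shortest_path(_GRAPH, source, target)
    except nx.NetworkXNoPath:
        raise UntranslatableError(source.name, target.name) from None
    return [_GRAPH.edges[a, b]["edge"] for a, b in zip(nodes, nodes[1:])]


def translate_axiom(ax, source: LogicId, target: LogicId):
    for edge in _edge_path(source, target):
        ax = edge.sentence_map(ax)
    return ax


def translate_signature(sig: Signature, source: LogicId,
                        target: LogicId) -> Signature:
    for edge in _edge_path(source, target):
        sig = edge.signature_map(sig)
    return sig


def translate(ontology: Ontology, target: LogicId) -> Ontology:
    """Translate a module along the graph to ``target``.

    Raises :class:`~minidol.errors.UntranslatableError` when no directed
    path exists (e.g. DL back into EL).
    """
    if ontology.logic == target:
        return ontology
    path = _edge_path(ontology.logic, target)  # raises if absent
    out = ontology.copy()
    out.logic = target
    out.signature = translate_signature(ontology.signature,
                                        ontology.logic, target)
    out.axioms = [translate_axiom(ax, ontology.logic, target)
                  for ax in ontology.axioms]
    del path
    return out


def common_supralogic(a: LogicId, b: LogicId) -> LogicId:
    """Least logic both sides can be translated into for joint reasoning.

    Sub-Boolean logics are lifted to DL first: the EL fragment has no full
    negation, so interpretation checking between propositional and EL
    modules happens in the induced DL setting.
    """
    top = max(a, b)
    if top in (LogicId.PROP, LogicId.EL):
        return LogicId.DL
    return top


def check_interpretation(source: Ontology, target: Ontology,
                         edge: Optional[TranslationEdge] = None,
                         bound: int = 4, engine: str = "ground"):
    """Verify an interpretation link: every translated source axiom must be
    bounded-entailed by the target ontology.

    Both sides are translated into their common supralogic (the induced
    homogeneous interpretation).  Returns a
    :class:`~minidol.reasoner.BoundedVerdict`; a refutation carries the
    countermodel and the failing axiom.  An inconsistent target (within the
    bound) is flagged on the verdict, since entailment then trivialises.
    """
    from .reasoner import BoundedVerdict, entails, find_model

    lift = common_supralogic(source.logic, target.logic)
    if edge is not None and edge.target > lift:
        lift = edge.target
    src = translate(source, lift)
    tgt = translate(target, lift)
    tgt.signature = tgt.signature.union(src.signature)

    warning = None
    if find_model(tgt, bound, engine=engine) is None:
        warning = "target ontology is inconsistent within the bound"

    for ax in src.axioms:
        verdict = entails(tgt, ax, bound, engine=engine)
        if verdict.status != "holds_up_to_bound":
            verdict.goal = ax
            verdict.message = warning
            return verdict
    return BoundedVerdict(status="holds_up_to_bound", bound=bound,
                          message=warning)
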