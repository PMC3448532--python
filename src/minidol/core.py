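"""Abstract syntax, signatures and finite-model satisfaction.

The toolkit works with a linear tower of logics:

    PROP < EL < DL < EXPDL < FOL < CL

* **PROP** — propositional logic over a finite set of proposition symbols.
* **EL** — a sub-Boolean description logic: conjunction, existential
  restriction and nominals, no negation/union/universal/cardinality and no
  asymmetric roles.
* **DL** — an expressive OWL-style description logic (Boolean concept
  constructors, qualified exact cardinality, nominals, inverse roles, role
  characteristics, property chains) subject to the OWL regularity
  restrictions, which :func:`check_profile` reports on.
* **EXPDL** — the same concept language as DL but with the OWL regularity
  restrictions deliberately relaxed (e.g. a role may be both transitive and
  asymmetric, chains may feed non-simple roles).
* **FOL** — first-order logic with equality over unary/binary/n-ary
  predicates and individual constants.
* **CL** — FOL extended with quantification over unary predicate variables
  (the second-order feature needed for category guards and fusion).

Semantics throughout is classical Tarskian satisfaction over *finite*
interpretations; second-order quantifiers are evaluated by enumerating all
subsets of the domain and are refused beyond a configurable domain size.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Iterator, Optional, Union

from .errors import BoundExceededError, SignatureClashError

__all__ = [
    "LogicId", "Signature", "Ontology", "FiniteInterpretation",
    "Top", "Bottom", "Atomic", "Not", "And", "Or", "Implies", "Some", "Only",
    "Exactly", "Nominal", "Inv",
    "SubClassOf", "EquivalentClasses", "DisjointUnion", "DisjointClasses",
    "Transitive", "Asymmetric", "SubPropertyOf", "SubPropertyChain",
    "ClassAssertion", "RoleAssertion", "DifferentFrom", "PropAxiom",
    "Var", "Const", "PredAtom", "Eq", "ExtEq",
    "FNot", "FAnd", "FOr", "FImplies", "FIff", "ForallI", "ExistsI",
    "ForallP", "ExistsP",
    "concept_extension", "satisfies", "fol_eval", "check_profile",
    "ProfileViolation", "forbidden_constructs", "axiom_signature_names",
]


class LogicId(IntEnum):
    """Logic identifiers, ordered by increasing expressivity."""

    PROP = 0
    EL = 1
    DL = 2
    EXPDL = 3
    FOL = 4
    CL = 5

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


# ---------------------------------------------------------------------------
# Formula AST.  All nodes are frozen (hashable, comparable by value).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Top:
    pass


@dataclass(frozen=True)
class Bottom:
    pass


@dataclass(frozen=True)
class Atomic:
    """Atomic concept (or proposition symbol, in PROP formulas)."""

    name: str


@dataclass(frozen=True)
class Not:
    arg: "Concept"


@dataclass(frozen=True)
class And:
    args: tuple


@dataclass(frozen=True)
class Or:
    args: tuple


@dataclass(frozen=True)
class Implies:
    """Propositional implication; only admitted inside PROP axioms."""

    left: "Concept"
    right: "Concept"


@dataclass(frozen=True)
class Inv:
    """Inverse of a role name."""

    role: str


Role = Union[str, Inv]


@dataclass(frozen=True)
class Some:
    role: Role
    filler: "Concept"


@dataclass(frozen=True)
class Only:
    role: Role
    filler: "Concept"


@dataclass(frozen=True)
class Exactly:
    n: int
    role: Role
    filler: "Concept"


@dataclass(frozen=True)
class Nominal:
    """Enumerated class {i1, ..., ik} of individual names."""

    individuals: tuple


Concept = Union[Top, Bottom, Atomic, Not, And, Or, Implies, Some, Only,
                Exactly, Nominal]


# --- DL / Prop axioms -------------------------------------------------------

@dataclass(frozen=True)
class SubClassOf:
    sub: Concept
    sup: Concept


@dataclass(frozen=True)
class EquivalentClasses:
    left: Concept
    right: Concept


@dataclass(frozen=True)
class DisjointUnion:
    """``name`` is equivalent to the pairwise-disjoint union of ``parts``."""

    name: str
    parts: tuple


@dataclass(frozen=True)
class DisjointClasses:
    parts: tuple


@dataclass(frozen=True)
class Transitive:
    role: str


@dataclass(frozen=True)
class Asymmetric:
    role: str


@dataclass(frozen=True)
class SubPropertyOf:
    sub: str
    sup: str


@dataclass(frozen=True)
class SubPropertyChain:
    """chain[0] o chain[1] o ... is a subproperty of ``sup``."""

    chain: tuple
    sup: str


@dataclass(frozen=True)
class ClassAssertion:
    concept: Concept
    individual: str


@dataclass(frozen=True)
class RoleAssertion:
    role: str
    subject: str
    object: str


@dataclass(frozen=True)
class DifferentFrom:
    a: str
    b: str


@dataclass(frozen=True)
class PropAxiom:
    """A propositional formula asserted to hold (PROP modules)."""

    formula: Concept


# --- FOL / CL ---------------------------------------------------------------

@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Const:
    name: str


Term = Union[Var, Const]


@dataclass(frozen=True)
class PredAtom:
    """Application of a predicate (name or bound predicate variable).

    ``pred`` is a string (declared predicate) or a :class:`Var` bound by a
    second-order quantifier.  Arguments are terms, or :class:`Var` names of
    predicate variables for mixed second-order predicates such as ``fusion``.
    """

    pred: Union[str, Var]
    args: tuple


@dataclass(frozen=True)
class Eq:
    left: Term
    right: Term


@dataclass(frozen=True)
class ExtEq:
    """Extension equality between a predicate variable and a unary predicate."""

    var: str
    pred: str


@dataclass(frozen=True)
class FNot:
    arg: "Formula"


@dataclass(frozen=True)
class FAnd:
    args: tuple


@dataclass(frozen=True)
class FOr:
    args: tuple


@dataclass(frozen=True)
class FImplies:
    left: "Formula"
    right: "Formula"


@dataclass(frozen=True)
class FIff:
    left: "Formula"
    right: "Formula"


@dataclass(frozen=True)
class ForallI:
    vars: tuple
    body: "Formula"


@dataclass(frozen=True)
class ExistsI:
    vars: tuple
    body: "Formula"


@dataclass(frozen=True)
class ForallP:
    """Universal quantification over unary predicate variables."""

    vars: tuple
    body: "Formula"


@dataclass(frozen=True)
class ExistsP:
    vars: tuple
    body: "Formula"


Formula = object  # any axiom/formula node above

FOL_NODES = (PredAtom, Eq, ExtEq, FNot, FAnd, FOr, FImplies, FIff,
             ForallI, ExistsI, ForallP, ExistsP)
SO_NODES = (ForallP, ExistsP, ExtEq)


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """A finite vocabulary, partitioned into disjoint name categories."""

    concepts: set = field(default_factory=set)
    roles: set = field(default_factory=set)
    individuals: set = field(default_factory=set)
    props: set = field(default_factory=set)
    predicates: set = field(default_factory=set)  # {(name, arity >= 1)}

    def validate(self) -> None:
        """Raise :class:`SignatureClashError` on names in two categories."""
        cats = {
            "concept": self.concepts,
            "role": self.roles,
            "individual": self.individuals,
            "prop": self.props,
            "predicate": {n for n, _ in self.predicates},
        }
        seen: dict = {}
        for cat, names in cats.items():
            for n in names:
                if n in seen and seen[n] != cat:
                    raise SignatureClashError(
                        f"name {n!r} declared both as {seen[n]} and as {cat}")
                seen[n] = cat

    def union(self, other: "Signature") -> "Signature":
        sig = Signature(
            concepts=self.concepts | other.concepts,
            roles=self.roles | other.roles,
            individuals=self.individuals | other.individuals,
            props=self.props | other.props,
            predicates=self.predicates | other.predicates,
        )
        sig.validate()
        return sig

    def copy(self) -> "Signature":
        return Signature(set(self.concepts), set(self.roles),
                         set(self.individuals), set(self.props),
                         set(self.predicates))

    def all_names(self) -> set:
        return (self.concepts | self.roles | self.individuals | self.props
                | {n for n, _ in self.predicates})

    def to_dict(self) -> dict:
        return {
            "concepts": sorted(self.concepts),
            "roles": sorted(self.roles),
            "individuals": sorted(self.individuals),
            "props": sorted(self.props),
            "predicates": sorted([list(p) for p in self.predicates]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(set(d.get("concepts", ())), set(d.get("roles", ())),
                   set(d.get("individuals", ())), set(d.get("props", ())),
                   {(n, a) for n, a in d.get("predicates", ())})


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

@dataclass
class Ontology:
    """A named module: a logic, a signature and a list of axioms.

    ``imports`` records ``(module name, translation edge name or None)``
    pairs; they are resolved by the distributed-ontology layer
    (:mod:`minidol.dol`), not here.
    """

    name: str
    logic: LogicId
    signature: Signature = field(default_factory=Signature)
    axioms: list = field(default_factory=list)
    imports: list = field(default_factory=list)
    annotations: dict = field(default_factory=dict)
    circ_block: object = None  # attached minimise/vary/%implies block

    def copy(self) -> "Ontology":
        return Ontology(self.name, self.logic, self.signature.copy(),
                        list(self.axioms), list(self.imports),
                        dict(self.annotations), self.circ_block)

    def to_json(self) -> str:
        from .printer import ontology_to_dict
        return json.dumps(ontology_to_dict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Finite interpretations
# ---------------------------------------------------------------------------

@dataclass
class FiniteInterpretation:
    """A finite structure over (a superset of) an ontology's signature.

    * ``domain`` — non-empty ordered tuple of hashable element ids.
    * ``concept_ext`` — concept name -> frozenset of elements.
    * ``role_ext`` — role name -> frozenset of (element, element) pairs.
    * ``pred_ext`` — (predicate name, arity) -> extension; bare elements
      for arity 1, argument tuples otherwise.  Tuple components may be
      elements or frozensets of elements (the latter back mixed
      second-order predicates such as ``fusion``).
    * ``indiv`` — individual name -> element (total on the signature).
    * ``prop_val`` — proposition symbol -> bool.
    """

    domain: tuple
    concept_ext: dict = field(default_factory=dict)
    role_ext: dict = field(default_factory=dict)
    pred_ext: dict = field(default_factory=dict)
    indiv: dict = field(default_factory=dict)
    prop_val: dict = field(default_factory=dict)

    def __post_init__(self):
        self.domain = tuple(self.domain)
        if not self.domain:
            raise ValueError("interpretation domain must be non-empty")

    # Unary/binary lookups fall back to pred_ext so that one structure can
    # serve an ontology and its first-order translation.
    def unary(self, name: str) -> frozenset:
        if name in self.concept_ext:
            return frozenset(self.concept_ext[name])
        return frozenset(self.pred_ext.get((name, 1), ()))

    def binary(self, name: str) -> frozenset:
        if name in self.role_ext:
            return frozenset(self.role_ext[name])
        return frozenset(self.pred_ext.get((name, 2), ()))

    def to_dict(self) -> dict:
        def enc(x):
            if isinstance(x, frozenset):
                return {"set": sorted(x, key=repr)}
            return x

        return {
            "domain": list(self.domain),
            "concept_ext": {c: sorted(v, key=repr)
                            for c, v in sorted(self.concept_ext.items())},
            "role_ext": {r: sorted([list(p) for p in v])
                         for r, v in sorted(self.role_ext.items())},
            "pred_ext": {f"{n}/{a}": sorted([[enc(c) for c in t] for t in v],
                                            key=repr)
                         for (n, a), v in sorted(self.pred_ext.items())},
            "indiv": dict(sorted(self.indiv.items())),
            "prop_val": dict(sorted(self.prop_val.items())),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def role_pairs(interp: FiniteInterpretation, role: Role) -> frozenset:
    if isinstance(role, Inv):
        return frozenset((b, a) for a, b in interp.binary(role.role))
    return interp.binary(role)


def concept_extension(interp: FiniteInterpretation, c: Concept) -> frozenset:
    """Set-theoretic evaluation of a concept over a finite interpretation."""
    dom = frozenset(interp.domain)
    if isinstance(c, Top):
        return dom
    if isinstance(c, Bottom):
        return frozenset()
    if isinstance(c, Atomic):
        return interp.unary(c.name)
    if isinstance(c, Not):
        return dom - concept_extension(interp, c.arg)
    if isinstance(c, And):
        out = dom
        for a in c.args:
            out &= concept_extension(interp, a)
        return out
    if isinstance(c, Or):
        out = frozenset()
        for a in c.args:
            out |= concept_extension(interp, a)
        return out
    if isinstance(c, Implies):
        return concept_extension(interp, Or((Not(c.left), c.right)))
    if isinstance(c, Some):
        pairs = role_pairs(interp, c.role)
        filler = concept_extension(interp, c.filler)
        return frozenset(a for a, b in pairs if b in filler)
    if isinstance(c, Only):
        pairs = role_pairs(interp, c.role)
        filler = concept_extension(interp, c.filler)
        bad = frozenset(a for a, b in pairs if b not in filler)
        return dom - bad
    if isinstance(c, Exactly):
        pairs = role_pairs(interp, c.role)
        filler = concept_extension(interp, c.filler)
        out = set()
        for d in dom:
            succ = sum(1 for a, b in pairs if a == d and b in filler)
            if succ == c.n:
                out.add(d)
        return frozenset(out)
    if isinstance(c, Nominal):
        return frozenset(interp.indiv[i] for i in c.individuals)
    raise TypeError(f"not a concept: {c!r}")


def _prop_eval(interp: FiniteInterpretation, f: Concept) -> bool:
    if isinstance(f, Atomic):
        return bool(interp.prop_val.get(f.name, False))
    if isinstance(f, Top):
        return True
    if isinstance(f, Bottom):
        return False
    if isinstance(f, Not):
        return not _prop_eval(interp, f.arg)
    if isinstance(f, And):
        return all(_prop_eval(interp, a) for a in f.args)
    if isinstance(f, Or):
        return any(_prop_eval(interp, a) for a in f.args)
    if isinstance(f, Implies):
        return (not _prop_eval(interp, f.left)) or _prop_eval(interp, f.right)
    raise TypeError(f"not a propositional formula: {f!r}")


def _subsets(domain: tuple) -> Iterator[frozenset]:
    for r in range(len(domain) + 1):
        for combo in itertools.combinations(domain, r):
            yield frozenset(combo)


def _term_value(interp: FiniteInterpretation, t, env: dict):
    if isinstance(t, Var):
        if t.name not in env:
            raise ValueError(f"unbound variable {t.name!r}")
        return env[t.name]
    if isinstance(t, Const):
        return interp.indiv[t.name]
    raise TypeError(f"not a term: {t!r}")


def fol_eval(interp: FiniteInterpretation, f, env: Optional[dict] = None,
             so_bound: int = 8) -> bool:
    """Evaluate a first-order / second-order formula.

    ``env`` maps individual variables to domain elements and predicate
    variables to frozensets of elements.  Second-order quantifiers enumerate
    all ``2^|domain|`` subsets and are refused when the domain exceeds
    ``so_bound``.
    """
    env = env or {}
    if isinstance(f, PredAtom):
        vals = tuple(_term_value(interp, a, env) for a in f.args)
        if isinstance(f.pred, Var):
            ext = env.get(f.pred.name)
            if not isinstance(ext, frozenset):
                raise ValueError(f"unbound predicate variable {f.pred.name!r}")
            return vals[0] in ext
        arity = len(vals)
        has_set_arg = any(isinstance(v, frozenset) for v in vals)
        if arity == 1 and not has_set_arg:
            return vals[0] in interp.unary(f.pred)
        if arity == 2 and not has_set_arg:
            return vals in interp.binary(f.pred)
        return vals in interp.pred_ext.get((f.pred, arity), frozenset())
    if isinstance(f, Eq):
        return _term_value(interp, f.left, env) == _term_value(interp, f.right, env)
    if isinstance(f, ExtEq):
        ext = env.get(f.var)
        if not isinstance(ext, frozenset):
            raise ValueError(f"unbound predicate variable {f.var!r}")
        return ext == interp.unary(f.pred)
    if isinstance(f, FNot):
        return not fol_eval(interp, f.arg, env, so_bound)
    if isinstance(f, FAnd):
        return all(fol_eval(interp, a, env, so_bound) for a in f.args)
    if isinstance(f, FOr):
        return any(fol_eval(interp, a, env, so_bound) for a in f.args)
    if isinstance(f, FImplies):
        return (not fol_eval(interp, f.left, env, so_bound)) or \
            fol_eval(interp, f.right, env, so_bound)
    if isinstance(f, FIff):
        return fol_eval(interp, f.left, env, so_bound) == \
            fol_eval(interp, f.right, env, so_bound)
    if isinstance(f, (ForallI, ExistsI)):
        combos = itertools.product(interp.domain, repeat=len(f.vars))
        results = (fol_eval(interp, f.body, {**env, **dict(zip(f.vars, c))},
                            so_bound) for c in combos)
        return all(results) if isinstance(f, ForallI) else any(results)
    if isinstance(f, (ForallP, ExistsP)):
        if len(interp.domain) > so_bound:
            raise BoundExceededError(
                f"second-order evaluation refused: |domain|="
                f"{len(interp.domain)} exceeds bound {so_bound}")
        combos = itertools.product(list(_subsets(interp.domain)),
                                   repeat=len(f.vars))
        results = (fol_eval(interp, f.body, {**env, **dict(zip(f.vars, c))},
                            so_bound) for c in combos)
        return all(results) if isinstance(f, ForallP) else any(results)
    # Mixed second-order predicate variables appearing as arguments are
    # routed through PredAtom above; anything else is malformed.
    raise TypeError(f"not a formula: {f!r}")


def satisfies(interp: FiniteInterpretation, axiom, so_bound: int = 8) -> bool:
    """Tarskian satisfaction of one axiom over a finite interpretation.

    Deterministic and total for domains within ``so_bound`` (second-order
    quantification over larger domains raises
    :class:`~minidol.errors.BoundExceededError`).
    """
    if isinstance(axiom, PropAxiom):
        return _prop_eval(interp, axiom.formula)
    if isinstance(axiom, SubClassOf):
        return concept_extension(interp, axiom.sub) <= \
            concept_extension(interp, axiom.sup)
    if isinstance(axiom, EquivalentClasses):
        return concept_extension(interp, axiom.left) == \
            concept_extension(interp, axiom.right)
    if isinstance(axiom, DisjointUnion):
        parts = [concept_extension(interp, p) for p in axiom.parts]
        union = frozenset().union(*parts) if parts else frozenset()
        if interp.unary(axiom.name) != union:
            return False
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                if parts[i] & parts[j]:
                    return False
        return True
    if isinstance(axiom, DisjointClasses):
        parts = [concept_extension(interp, p) for p in axiom.parts]
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                if parts[i] & parts[j]:
                    return False
        return True
    if isinstance(axiom, Transitive):
        pairs = interp.binary(axiom.role)
        return all((a, c) in pairs
                   for a, b in pairs for b2, c in pairs if b == b2)
    if isinstance(axiom, Asymmetric):
        pairs = interp.binary(axiom.role)
        return all((b, a) not in pairs for a, b in pairs)
    if isinstance(axiom, SubPropertyOf):
        return interp.binary(axiom.sub) <= interp.binary(axiom.sup)
    if isinstance(axiom, SubPropertyChain):
        sup = interp.binary(axiom.sup)
        pairs = {(d, d) for d in interp.domain}  # identity chain seed
        for r in axiom.chain:
            ext = interp.binary(r)
            pairs = {(a, c) for a, b in pairs for b2, c in ext if b == b2}
        return pairs <= sup
    if isinstance(axiom, ClassAssertion):
        return interp.indiv[axiom.individual] in \
            concept_extension(interp, axiom.concept)
    if isinstance(axiom, RoleAssertion):
        return (interp.indiv[axiom.subject], interp.indiv[axiom.object]) in \
            interp.binary(axiom.role)
    if isinstance(axiom, DifferentFrom):
        return interp.indiv[axiom.a] != interp.indiv[axiom.b]
    if isinstance(axiom, FOL_NODES):
        return fol_eval(interp, axiom, {}, so_bound)
    raise TypeError(f"not an axiom: {axiom!r}")


def satisfies_all(interp: FiniteInterpretation, axioms: Iterable,
                  so_bound: int = 8) -> bool:
    return all(satisfies(interp, ax, so_bound) for ax in axioms)


# ---------------------------------------------------------------------------
# Expressivity (per-logic construct admission)
# ---------------------------------------------------------------------------

_EL_FORBIDDEN_CONCEPTS = (Not, Or, Only, Exactly, Implies)


def _walk_concepts(node) -> Iterator:
    yield node
    for attr in ("arg", "sub", "sup", "left", "right", "filler", "formula",
                 "concept", "body"):
        child = getattr(node, attr, None)
        if child is not None and not isinstance(child, (str, int, tuple)):
            yield from _walk_concepts(child)
    for attr in ("args", "parts", "vars", "chain"):
        children = getattr(node, attr, None)
        if isinstance(children, tuple):
            for ch in children:
                if not isinstance(ch, (str, int)):
                    yield from _walk_concepts(ch)


def forbidden_constructs(axiom, logic: LogicId) -> list:
    """Names of constructs in ``axiom`` that ``logic`` does not admit."""
    out = []
    nodes = list(_walk_concepts(axiom))
    if logic == LogicId.PROP:
        for n in nodes:
            if not isinstance(n, (PropAxiom, Atomic, Not, And, Or, Implies,
                                  Top, Bottom)):
                out.append(type(n).__name__)
        return out
    if isinstance(axiom, PropAxiom):
        return ["PropAxiom"]
    if logic in (LogicId.EL, LogicId.DL, LogicId.EXPDL):
        for n in nodes:
            if isinstance(n, FOL_NODES):
                out.append(type(n).__name__)
            elif logic == LogicId.EL:
                if isinstance(n, _EL_FORBIDDEN_CONCEPTS):
                    out.append(type(n).__name__)
                elif isinstance(n, Asymmetric):
                    out.append("Asymmetric")
        return out
    # FOL / CL: DL axioms must have been translated away.
    for n in nodes:
        if isinstance(n, SO_NODES) and logic != LogicId.CL:
            out.append(type(n).__name__)
    if not isinstance(axiom, FOL_NODES):
        out.append(type(axiom).__name__)
    return out


# ---------------------------------------------------------------------------
# Names used by an axiom (well-formedness against a signature)
# ---------------------------------------------------------------------------

def axiom_signature_names(axiom) -> dict:
    """Collect the signature names an axiom uses, per category."""
    used = {"concepts": set(), "roles": set(), "individuals": set(),
            "props": set(), "predicates": set()}

    bound: set = set()

    def visit(node, in_prop: bool, pred_vars: set):
        if isinstance(node, PropAxiom):
            visit(node.formula, True, pred_vars)
            return
        if isinstance(node, Atomic):
            (used["props"] if in_prop else used["concepts"]).add(node.name)
            return
        if isinstance(node, Nominal):
            used["individuals"].update(node.individuals)
            return
        if isinstance(node, (Some, Only, Exactly)):
            r = node.role.role if isinstance(node.role, Inv) else node.role
            used["roles"].add(r)
            visit(node.filler, in_prop, pred_vars)
            return
        if isinstance(node, DisjointUnion):
            used["concepts"].add(node.name)
            for p in node.parts:
                visit(p, in_prop, pred_vars)
            return
        if isinstance(node, (Transitive, Asymmetric)):
            used["roles"].add(node.role)
            return
        if isinstance(node, SubPropertyOf):
            used["roles"].update((node.sub, node.sup))
            return
        if isinstance(node, SubPropertyChain):
            used["roles"].update(node.chain)
            used["roles"].add(node.sup)
            return
        if isinstance(node, ClassAssertion):
            used["individuals"].add(node.individual)
            visit(node.concept, in_prop, pred_vars)
            return
        if isinstance(node, RoleAssertion):
            used["roles"].add(node.role)
            used["individuals"].update((node.subject, node.object))
            return
        if isinstance(node, DifferentFrom):
            used["individuals"].update((node.a, node.b))
            return
        if isinstance(node, PredAtom):
            if isinstance(node.pred, str):
                used["predicates"].add((node.pred, len(node.args)))
            for a in node.args:
                if isinstance(a, Const):
                    used["individuals"].add(a.name)
            return
        if isinstance(node, ExtEq):
            used["predicates"].add((node.pred, 1))
            return
        if isinstance(node, Eq):
            for t in (node.left, node.right):
                if isinstance(t, Const):
                    used["individuals"].add(t.name)
            return
        for attr in ("arg", "sub", "sup", "left", "right", "formula", "body"):
            child = getattr(node, attr, None)
            if child is not None and not isinstance(child, (str, int, tuple)):
                visit(child, in_prop, pred_vars)
        for attr in ("args", "parts"):
            children = getattr(node, attr, None)
            if isinstance(children, tuple):
                for ch in children:
                    if not isinstance(ch, (str, int)):
                        visit(ch, in_prop, pred_vars)

    visit(axiom, False, bound)
    return used


# ---------------------------------------------------------------------------
# OWL profile (regularity) checking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileViolation:
    """One OWL-regularity violation found by :func:`check_profile`."""

    kind: str       # "transitive-asymmetric" | "chain-super-in-restricted-context"
    role: str
    detail: str


def _cardinality_roles(axioms) -> set:
    out = set()
    for ax in axioms:
        for node in _walk_concepts(ax):
            if isinstance(node, Exactly):
                r = node.role.role if isinstance(node.role, Inv) else node.role
                out.add(r)
    return out


def check_profile(ontology: Ontology) -> list:
    """Report OWL-regularity violations in a flattened ontology.

    Two rules are checked, mirroring OWL 2's global restrictions on role
    axioms: (i) no role may be both transitive (directly, or via a chain
    ``r o r -> r``) and asymmetric; (ii) the superproperty of a property
    chain may not occur in a cardinality restriction or be asymmetric.
    An empty list means the module is regular for its declared logic.
    """
    transitive, asymmetric, chain_supers = set(), set(), set()
    for ax in ontology.axioms:
        if isinstance(ax, Transitive):
            transitive.add(ax.role)
        elif isinstance(ax, Asymmetric):
            asymmetric.add(ax.role)
        elif isinstance(ax, SubPropertyChain):
            chain_supers.add(ax.sup)
            if ax.chain == (ax.sup, ax.sup):
                transitive.add(ax.sup)
    card_roles = _cardinality_roles(ontology.axioms)

    out = []
    for r in sorted(transitive & asymmetric):
        out.append(ProfileViolation(
            "transitive-asymmetric", r,
            f"role {r!r} is declared both transitive and asymmetric"))
    for r in sorted(chain_supers):
        if r in asymmetric:
            out.append(ProfileViolation(
                "chain-super-in-restricted-context", r,
                f"chain superproperty {r!r} is asymmetric"))
        if r in card_roles:
            out.append(ProfileViolation(
                "chain-super-in-restricted-context", r,
                f"chain superproperty {r!r} occurs in a cardinality "
                f"restriction"))
    return out
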