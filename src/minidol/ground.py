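"""Grounding of ontologies over a fixed finite domain into CNF.

Every axiom is expanded over the domain ``{0, ..., n-1}`` into a Boolean
formula over atoms

* ``('c', A, d)`` — element ``d`` belongs to concept / unary predicate ``A``,
* ``('r', r, d, e)`` — ``(d, e)`` belongs to role / binary predicate ``r``,
* ``('p', P, args)`` — an n-ary or mixed second-order predicate tuple,
* ``('i', a, d)`` — individual ``a`` denotes element ``d`` (exactly one
  ``d`` per individual),
* ``('v', p)`` — proposition symbol ``p`` is true,

then Tseitin-transformed into clauses for the DPLL solver.  Second-order
quantifiers are finitely expanded over all subsets of the domain (the
domain bound makes this exact), so the Common Logic fragment grounds like
everything else.
"""

from __future__ import annotations

import itertools
from .core import (And, Asymmetric, Atomic, Bottom, ClassAssertion, Const,
                   DifferentFrom, DisjointClasses, DisjointUnion, Eq,
                   EquivalentClasses, Exactly, ExistsI, ExistsP, ExtEq, FAnd,
                   FIff, FImplies, FNot, FOr, FiniteInterpretation, ForallI,
                   ForallP, Implies, Inv, Nominal, Not, Only, Or, PredAtom,
                   PropAxiom, RoleAssertion, Signature, Some, SubClassOf,
                   SubPropertyChain, SubPropertyOf, Top, Transitive, Var)
from .errors import BoundExceededError
from .sat import Solver

__all__ = ["Grounder"]

TRUE = True
FALSE = False


def _and(parts):
    parts = [p for p in parts if p is not TRUE]
    if any(p is FALSE for p in parts):
        return FALSE
    if not parts:
        return TRUE
    if len(parts) == 1:
        return parts[0]
    return ("and", tuple(parts))


def _or(parts):
    parts = [p for p in parts if p is not FALSE]
    if any(p is TRUE for p in parts):
        return TRUE
    if not parts:
        return FALSE
    if len(parts) == 1:
        return parts[0]
    return ("or", tuple(parts))


def _not(p):
    if p is TRUE:
        return FALSE
    if p is FALSE:
        return TRUE
    if isinstance(p, tuple) and p[0] == "not":
        return p[1]
    return ("not", p)


def _imp(a, b):
    return _or([_not(a), b])


def _iff(a, b):
    return _and([_imp(a, b), _imp(b, a)])


class Grounder:
    """Ground an ontology's axioms over ``n`` domain elements."""

    def __init__(self, signature: Signature, n: int, so_bound: int = 8,
                 pin_first_individual: bool = True):
        self.sig = signature
        self.n = n
        self.domain = tuple(range(n))
        self.so_bound = so_bound
        self.solver = Solver()
        self.pool: dict = {}
        self.rev: dict = {}  # var -> key
        self._tseitin_cache: dict = {}
        self._declare_individuals(pin_first_individual)

    # -- variables ---------------------------------------------------------
    def vid(self, key) -> int:
        v = self.pool.get(key)
        if v is None:
            v = self.solver.new_var()
            self.pool[key] = v
            self.rev[v] = key
        return v

    def lit(self, key):
        return ("lit", self.vid(key))

    def _declare_individuals(self, pin_first: bool) -> None:
        inds = sorted(self.sig.individuals)
        for a in inds:
            vs = [self.vid(("i", a, d)) for d in self.domain]
            self.solver.add_clause(vs)
            for x, y in itertools.combinations(vs, 2):
                self.solver.add_clause([-x, -y])
        if pin_first and inds:
            # Domain elements are interchangeable a priori, so individual
            # denotations can be restricted to canonical (value-precedence)
            # form: the j-th individual may use element d > 0 only if some
            # earlier individual uses element d-1.  Every interpretation is
            # isomorphic to exactly one canonical one, so existence and
            # minimality questions are unaffected.
            for j, a in enumerate(inds):
                for d in self.domain:
                    if d > j:
                        self.solver.add_clause([-self.vid(("i", a, d))])
                    elif d >= 1:
                        clause = [-self.vid(("i", a, d))]
                        clause += [self.vid(("i", inds[k], d - 1))
                                   for k in range(j)]
                        self.solver.add_clause(clause)

    # -- concepts ----------------------------------------------------------
    def _role_lit(self, role, d, e):
        if isinstance(role, Inv):
            return self.lit(("r", role.role, e, d))
        return self.lit(("r", role, d, e))

    def enc_concept(self, c, d):
        if isinstance(c, Top):
            return TRUE
        if isinstance(c, Bottom):
            return FALSE
        if isinstance(c, Atomic):
            return self.lit(("c", c.name, d))
        if isinstance(c, Not):
            return _not(self.enc_concept(c.arg, d))
        if isinstance(c, And):
            return _and([self.enc_concept(a, d) for a in c.args])
        if isinstance(c, Or):
            return _or([self.enc_concept(a, d) for a in c.args])
        if isinstance(c, Implies):
            return _imp(self.enc_concept(c.left, d),
                        self.enc_concept(c.right, d))
        if isinstance(c, Some):
            return _or([_and([self._role_lit(c.role, d, e),
                              self.enc_concept(c.filler, e)])
                        for e in self.domain])
        if isinstance(c, Only):
            return _and([_imp(self._role_lit(c.role, d, e),
                              self.enc_concept(c.filler, e))
                         for e in self.domain])
        if isinstance(c, Exactly):
            members = {e: _and([self._role_lit(c.role, d, e),
                                self.enc_concept(c.filler, e)])
                       for e in self.domain}
            if c.n > self.n:
                return FALSE
            opts = []
            for inside in itertools.combinations(self.domain, c.n):
                ins = set(inside)
                opts.append(_and(
                    [members[e] for e in inside] +
                    [_not(members[e]) for e in self.domain if e not in ins]))
            return _or(opts)
        if isinstance(c, Nominal):
            return _or([self.lit(("i", i, d)) for i in c.individuals])
        raise TypeError(f"not a concept: {c!r}")

    # -- first-order formulas ----------------------------------------------
    def _enc_atom(self, pred, vals):
        """``vals``: domain elements and/or frozensets (second-order args)."""
        if isinstance(pred, Var):
            raise TypeError("unbound predicate variable in grounding")
        arity = len(vals)
        mixed = any(isinstance(v, frozenset) for v in vals)
        if arity == 1 and not mixed:
            return self.lit(("c", pred, vals[0]))
        if arity == 2 and not mixed:
            return self.lit(("r", pred, vals[0], vals[1]))
        return self.lit(("p", pred, tuple(vals)))

    def enc_fol(self, f, env: dict):
        if isinstance(f, PredAtom):
            return self._expand_atom(f.pred, list(f.args), env, [])
        if isinstance(f, Eq):
            return self._expand_eq(f.left, f.right, env)
        if isinstance(f, ExtEq):
            ext = env.get(f.var)
            if not isinstance(ext, frozenset):
                raise TypeError(f"unbound predicate variable {f.var!r}")
            return _and([_iff(self.lit(("c", f.pred, d)),
                              TRUE if d in ext else FALSE)
                         for d in self.domain])
        if isinstance(f, FNot):
            return _not(self.enc_fol(f.arg, env))
        if isinstance(f, FAnd):
            return _and([self.enc_fol(a, env) for a in f.args])
        if isinstance(f, FOr):
            return _or([self.enc_fol(a, env) for a in f.args])
        if isinstance(f, FImplies):
            return _imp(self.enc_fol(f.left, env), self.enc_fol(f.right, env))
        if isinstance(f, FIff):
            return _iff(self.enc_fol(f.left, env), self.enc_fol(f.right, env))
        if isinstance(f, (ForallI, ExistsI)):
            parts = []
            for combo in itertools.product(self.domain, repeat=len(f.vars)):
                env2 = dict(env)
                env2.update(zip(f.vars, combo))
                parts.append(self.enc_fol(f.body, env2))
            return _and(parts) if isinstance(f, ForallI) else _or(parts)
        if isinstance(f, (ForallP, ExistsP)):
            if self.n > self.so_bound:
                raise BoundExceededError(
                    f"second-order grounding refused: |domain|={self.n} "
                    f"exceeds bound {self.so_bound}")
            subsets = [frozenset(c) for r in range(self.n + 1)
                       for c in itertools.combinations(self.domain, r)]
            parts = []
            for combo in itertools.product(subsets, repeat=len(f.vars)):
                env2 = dict(env)
                env2.update(zip(f.vars, combo))
                parts.append(self.enc_fol(f.body, env2))
            return _and(parts) if isinstance(f, ForallP) else _or(parts)
        raise TypeError(f"not a first-order formula: {f!r}")

    def _expand_atom(self, pred, args, env, vals):
        """Resolve term arguments; constants expand over their denotation."""
        if not args:
            if isinstance(pred, Var):
                ext = env.get(pred.name)
                if not isinstance(ext, frozenset):
                    raise TypeError(
                        f"unbound predicate variable {pred.name!r}")
                return TRUE if vals[0] in ext else FALSE
            return self._enc_atom(pred, vals)
        head, rest = args[0], args[1:]
        if isinstance(head, Var):
            val = env.get(head.name)
            if val is None:
                raise TypeError(f"unbound variable {head.name!r}")
            return self._expand_atom(pred, rest, env, vals + [val])
        if isinstance(head, Const):
            return _or([_and([self.lit(("i", head.name, d)),
                              self._expand_atom(pred, rest, env, vals + [d])])
                        for d in self.domain])
        raise TypeError(f"not a term: {head!r}")

    def _expand_eq(self, left, right, env):
        def resolve(t):
            if isinstance(t, Var):
                return env.get(t.name)
            return t  # Const, expanded below

        a, b = resolve(left), resolve(right)
        if isinstance(a, Const) and isinstance(b, Const):
            return _or([_and([self.lit(("i", a.name, d)),
                              self.lit(("i", b.name, d))])
                        for d in self.domain])
        if isinstance(a, Const) or isinstance(b, Const):
            const, elem = (a, b) if isinstance(a, Const) else (b, a)
            return self.lit(("i", const.name, elem))
        return TRUE if a == b else FALSE

    # -- axioms ------------------------------------------------------------
    def enc_prop(self, f):
        if isinstance(f, Atomic):
            return self.lit(("v", f.name))
        if isinstance(f, Top):
            return TRUE
        if isinstance(f, Bottom):
            return FALSE
        if isinstance(f, Not):
            return _not(self.enc_prop(f.arg))
        if isinstance(f, And):
            return _and([self.enc_prop(a) for a in f.args])
        if isinstance(f, Or):
            return _or([self.enc_prop(a) for a in f.args])
        if isinstance(f, Implies):
            return _imp(self.enc_prop(f.left), self.enc_prop(f.right))
        raise TypeError(f"not a propositional formula: {f!r}")

    def enc_axiom_chunks(self, ax) -> list:
        """The axiom's grounding as a list of per-instance conjuncts.

        ``_and(chunks)`` is the full encoding; the chunk structure (one
        conjunct per domain element / tuple / quantifier binding) lets
        the circumscription engine reason about which ground atoms an
        axiom instance actually connects.
        """
        D = self.domain
        if isinstance(ax, PropAxiom):
            return [self.enc_prop(ax.formula)]
        if isinstance(ax, SubClassOf):
            return [_imp(self.enc_concept(ax.sub, d),
                         self.enc_concept(ax.sup, d)) for d in D]
        if isinstance(ax, EquivalentClasses):
            return [_iff(self.enc_concept(ax.left, d),
                         self.enc_concept(ax.right, d)) for d in D]
        if isinstance(ax, DisjointUnion):
            parts = list(ax.parts)
            out = []
            for d in D:
                per_d = [_iff(self.lit(("c", ax.name, d)),
                              _or([self.enc_concept(p, d) for p in parts]))]
                for p, q in itertools.combinations(parts, 2):
                    per_d.append(_not(_and([self.enc_concept(p, d),
                                            self.enc_concept(q, d)])))
                out.append(_and(per_d))
            return out
        if isinstance(ax, DisjointClasses):
            out = []
            for d in D:
                out.append(_and(
                    [_not(_and([self.enc_concept(p, d),
                                self.enc_concept(q, d)]))
                     for p, q in itertools.combinations(ax.parts, 2)]))
            return out
        if isinstance(ax, Transitive):
            r = ax.role
            return [_imp(_and([self.lit(("r", r, a, b)),
                               self.lit(("r", r, b, c))]),
                         self.lit(("r", r, a, c)))
                    for a in D for b in D for c in D]
        if isinstance(ax, Asymmetric):
            r = ax.role
            return [_not(_and([self.lit(("r", r, a, b)),
                               self.lit(("r", r, b, a))]))
                    for a in D for b in D]
        if isinstance(ax, SubPropertyOf):
            return [_imp(self.lit(("r", ax.sub, a, b)),
                         self.lit(("r", ax.sup, a, b)))
                    for a in D for b in D]
        if isinstance(ax, SubPropertyChain):
            k = len(ax.chain)
            out = []
            for path in itertools.product(D, repeat=k + 1):
                body = _and([self.lit(("r", r, path[i], path[i + 1]))
                             for i, r in enumerate(ax.chain)])
                out.append(_imp(body, self.lit(("r", ax.sup, path[0],
                                                path[-1]))))
            return out
        if isinstance(ax, ClassAssertion):
            return [_imp(self.lit(("i", ax.individual, d)),
                         self.enc_concept(ax.concept, d)) for d in D]
        if isinstance(ax, RoleAssertion):
            return [_imp(_and([self.lit(("i", ax.subject, d)),
                               self.lit(("i", ax.object, e))]),
                         self.lit(("r", ax.role, d, e)))
                    for d in D for e in D]
        if isinstance(ax, DifferentFrom):
            return [_not(_and([self.lit(("i", ax.a, d)),
                               self.lit(("i", ax.b, d))])) for d in D]
        if isinstance(ax, ForallI):
            out = []
            for combo in itertools.product(D, repeat=len(ax.vars)):
                out.append(self.enc_fol(ax.body, dict(zip(ax.vars, combo))))
            return out
        if isinstance(ax, ForallP):
            if self.n > self.so_bound:
                raise BoundExceededError(
                    f"second-order grounding refused: |domain|={self.n} "
                    f"exceeds bound {self.so_bound}")
            subsets = [frozenset(c) for r in range(self.n + 1)
                       for c in itertools.combinations(D, r)]
            out = []
            for combo in itertools.product(subsets, repeat=len(ax.vars)):
                out.append(self.enc_fol(ax.body, dict(zip(ax.vars, combo))))
            return out
        return [self.enc_fol(ax, {})]

    def enc_axiom(self, ax):
        return _and(self.enc_axiom_chunks(ax))

    def chunk_atoms(self, node) -> set:
        """All ground-atom variables occurring in a Boolean AST chunk."""
        out: set = set()

        def walk(nd):
            if nd is TRUE or nd is FALSE:
                return
            tag = nd[0]
            if tag == "lit":
                out.add(nd[1])
            elif tag == "not":
                walk(nd[1])
            else:
                for ch in nd[1]:
                    walk(ch)

        walk(node)
        return out

    # -- CNF ---------------------------------------------------------------
    def _tseitin(self, node) -> int:
        """Return a literal equivalent to ``node``, adding defining clauses."""
        if node is TRUE or node is FALSE:
            t = self.pool.get(("const", True))
            if t is None:
                t = self.vid(("const", True))
                self.solver.add_clause([t])
            return t if node is TRUE else -t
        if node[0] == "lit":
            return node[1]
        if node[0] == "not":
            return -self._tseitin(node[1])
        cached = self._tseitin_cache.get(node)
        if cached is not None:
            return cached
        lits = [self._tseitin(ch) for ch in node[1]]
        t = self.solver.new_var()
        if node[0] == "and":
            for li in lits:
                self.solver.add_clause([-t, li])
            self.solver.add_clause([t] + [-li for li in lits])
        else:  # or
            for li in lits:
                self.solver.add_clause([-li, t])
            self.solver.add_clause([-t] + lits)
        self._tseitin_cache[node] = t
        return t

    def assert_formula(self, node) -> None:
        """Assert a Boolean formula (conjunction spine flattened)."""
        if node is TRUE:
            return
        if node is FALSE:
            self.solver.add_clause([])
            return
        if isinstance(node, tuple) and node[0] == "and":
            for ch in node[1]:
                self.assert_formula(ch)
            return
        if isinstance(node, tuple) and node[0] == "or":
            # clause if all children are literals/negated literals
            lits = []
            for ch in node[1]:
                if isinstance(ch, tuple) and ch[0] == "lit":
                    lits.append(ch[1])
                elif (isinstance(ch, tuple) and ch[0] == "not"
                      and isinstance(ch[1], tuple) and ch[1][0] == "lit"):
                    lits.append(-ch[1][1])
                else:
                    lits = None
                    break
            if lits is not None:
                self.solver.add_clause(lits)
                return
        self.solver.add_clause([self._tseitin(node)])

    def assert_axioms(self, axioms) -> None:
        for ax in axioms:
            self.assert_formula(self.enc_axiom(ax))

    # -- decoding ----------------------------------------------------------
    def decode(self, assignment) -> FiniteInterpretation:
        concept_ext = {c: set() for c in self.sig.concepts}
        role_ext = {r: set() for r in self.sig.roles}
        pred_ext = {p: set() for p in self.sig.predicates}
        indiv = {}
        prop_val = {p: False for p in self.sig.props}
        for key, var in self.pool.items():
            if not assignment[var]:
                continue
            kind = key[0]
            if kind == "c":
                _, name, d = key
                if name in self.sig.concepts:
                    concept_ext.setdefault(name, set()).add(d)
                else:
                    # arity-1 predicate extensions hold bare elements
                    pred_ext.setdefault((name, 1), set()).add(d)
            elif kind == "r":
                _, name, d, e = key
                if name in self.sig.roles:
                    role_ext.setdefault(name, set()).add((d, e))
                else:
                    pred_ext.setdefault((name, 2), set()).add((d, e))
            elif kind == "p":
                _, name, vals = key
                pred_ext.setdefault((name, len(vals)), set()).add(vals)
            elif kind == "i":
                _, name, d = key
                indiv[name] = d
            elif kind == "v":
                prop_val[key[1]] = True
        return FiniteInterpretation(
            domain=self.domain,
            concept_ext={c: frozenset(v) for c, v in concept_ext.items()},
            role_ext={r: frozenset(v) for r, v in role_ext.items()},
            pred_ext={p: frozenset(v) for p, v in pred_ext.items()},
            indiv=indiv,
            prop_val=prop_val,
        )
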