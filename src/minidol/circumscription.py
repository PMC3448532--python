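"""Parallel predicate circumscription over bounded finite models.

Circumscriptive entailment restricts attention to models that are
*minimal* in a pre-order: ``I`` is preferred to ``J`` when both share the
same domain, individual denotations and extensions of all *fixed* symbols,
and the extension of every minimised concept in ``I`` is included in its
extension in ``J``.  Concepts not listed as minimised or varying are
fixed.  Role extensions (and the extensions of the varying concepts) move
freely between comparable models: minimising an "abnormality" concept may
re-route unasserted role facts, which is exactly what lets an unmeasured
tissue individual default to the normal class until evidence to the
contrary is added.

Unrestricted circumscription is undecidable already over weak description
logics; everything here is *bounded*-domain semantics, which keeps every
question finite and decidable, at the price of verdicts that are explicit
about their bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import (FiniteInterpretation, Ontology, Signature, satisfies,
                   satisfies_all)
from .errors import MiniDolError
from .reasoner import (BoundedVerdict, GroundContext, _check_bound,
                       _signature_with, entails, enumerate_models)

__all__ = ["CircumscriptionSpec", "preferred", "strictly_preferred",
           "minimal_models", "circ_entails"]


@dataclass(frozen=True)
class CircumscriptionSpec:
    """The (minimised, varying) partition of a signature's concept names.

    Everything else — the remaining concepts, individual denotations, the
    domain, proposition symbols and n-ary predicates — is fixed;
    role extensions vary.
    """

    minimised: frozenset = frozenset()
    varying: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "minimised", frozenset(self.minimised))
        object.__setattr__(self, "varying", frozenset(self.varying))
        overlap = self.minimised & self.varying
        if overlap:
            raise ValueError(
                f"minimised and varying overlap: {sorted(overlap)}")

    def fixed_concepts(self, signature: Signature) -> frozenset:
        return frozenset(signature.concepts) - self.minimised - self.varying

    @property
    def is_classical(self) -> bool:
        return not self.minimised


def _comparable(i: FiniteInterpretation, j: FiniteInterpretation,
                spec: CircumscriptionSpec) -> bool:
    if i.domain != j.domain or i.indiv != j.indiv or i.prop_val != j.prop_val:
        return False
    if i.pred_ext != j.pred_ext:
        return False
    fixed = (set(i.concept_ext) | set(j.concept_ext)) \
        - set(spec.minimised) - set(spec.varying)
    return all(i.unary(c) == j.unary(c) for c in fixed)


def preferred(i: FiniteInterpretation, j: FiniteInterpretation,
              spec: CircumscriptionSpec) -> bool:
    """``i <= j`` in the circumscription pre-order.

    True iff the structures are comparable (same domain, individual
    denotations and fixed extensions) and every minimised concept's
    extension in ``i`` is a subset of its extension in ``j``.
    Incomparable structures are simply unordered (False both ways).
    """
    if not _comparable(i, j, spec):
        return False
    return all(i.unary(m) <= j.unary(m) for m in spec.minimised)


def strictly_preferred(i: FiniteInterpretation, j: FiniteInterpretation,
                       spec: CircumscriptionSpec) -> bool:
    """``i < j``: preferred with at least one proper inclusion."""
    if not preferred(i, j, spec):
        return False
    return any(i.unary(m) < j.unary(m) for m in spec.minimised)


def minimal_models(ontology: Ontology, spec: CircumscriptionSpec,
                   bound: int, so_bound: int = 8) -> list:
    """All models within the bound that are minimal in the pre-order.

    Exhaustive (enumeration-engine) computation, intended for small
    signatures and bounds; every returned model is verified to admit no
    strictly preferred model.
    """
    _check_bound(ontology.axioms, bound)
    sig = ontology.signature
    all_models: list = []
    for n in range(1, bound + 1):
        all_models.extend(enumerate_models(ontology.axioms, sig, n,
                                           so_bound))
    out = []
    for m in all_models:
        if not any(strictly_preferred(other, m, spec)
                   for other in all_models):
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# circumscriptive entailment, grounding path
# ---------------------------------------------------------------------------

class _CircSearch:
    """Search for a *minimal* countermodel at one domain size.

    Counterexample-guided: find a model falsifying the goal, test its
    minimality with a second (preference) query against the same clause
    store, and when a strictly preferred model exists, learn a clause that
    rules out every countermodel to which the same repair applies — the
    learned clause mentions only the atoms of symbols that co-occur in an
    axiom with a changed symbol, so it generalises over all the unrelated
    parts of the structure.
    """

    def __init__(self, axioms, sig: Signature, spec: CircumscriptionSpec,
                 goal, n: int, so_bound: int, max_iterations: int = 20000):
        self.axioms = axioms
        self.spec = spec
        self.goal = goal
        self.so_bound = so_bound
        self.max_iterations = max_iterations
        self.ctx = GroundContext(axioms, sig, n, so_bound)
        self.g = self.ctx.grounder
        self.solver = self.g.solver
        self.goal_lit = self.ctx.goal_lit(goal)
        self.act = self.solver.new_var()  # activates learned clauses
        # per-instance ground atom sets, for clause generalisation
        self.chunks = []
        for ax in axioms:
            for chunk in self.g.enc_axiom_chunks(ax):
                atoms = self.g.chunk_atoms(chunk)
                if atoms:
                    self.chunks.append(atoms)
        self._classes = {v: self._classify_key(k)
                         for k, v in self.g.pool.items()}

    def _classify_key(self, key) -> str:
        kind = key[0]
        if kind == "r":
            return "vary"
        if kind == "c":
            name = key[1]
            if name in self.spec.minimised:
                return "min"
            if name in self.spec.varying:
                return "vary"
            return "fixed"
        if kind == "const":
            return "skip"
        return "fixed"  # i, v, p

    def _semantic_vars(self):
        return [v for v, cls in self._classes.items() if cls != "skip"]

    def run(self) -> Optional[FiniteInterpretation]:
        for _ in range(self.max_iterations):
            assignment = self.solver.solve(
                assumptions=(self.act, -self.goal_lit),
                keep_guard=(-self.act, self.goal_lit))
            if assignment is None:
                return None
            m_vals = {v: assignment[v] for v in self._semantic_vars()}
            p_vals = self._strictly_preferred(m_vals)
            if p_vals is None:
                model = self.g.decode(assignment)
                assert satisfies_all(model, self.axioms, self.so_bound) \
                    and not satisfies(model, self.goal, self.so_bound)
                return model
            self._learn(m_vals, p_vals)
        raise MiniDolError(
            "circumscription search budget exceeded; raise max_iterations")

    def _strictly_preferred(self, m_vals) -> Optional[dict]:
        """A model strictly below ``m`` in its comparability class, or
        ``None`` when ``m`` is minimal.  The search is biased (via phase
        hints) towards models close to ``m``, keeping repairs local."""
        assumptions = [-self.act]
        strict_candidates = []
        for v, val in m_vals.items():
            cls = self._classes[v]
            if cls == "fixed":
                assumptions.append(v if val else -v)
            elif cls == "min":
                if not val:
                    assumptions.append(-v)
                else:
                    strict_candidates.append(v)
        if not strict_candidates:
            return None  # nothing to shrink: m is minimal
        s = self.solver.new_var()
        self.solver.add_clause([-s] + [-v for v in strict_candidates])
        assignment = self.solver.solve(assumptions=assumptions + [s],
                                       phase=m_vals)
        if assignment is None:
            return None
        return {v: assignment[v] for v in m_vals}

    def _learn(self, m_vals, p_vals) -> None:
        """Exclude every countermodel the found repair also applies to.

        ``delta`` holds the ground atoms the preferred model changed
        (only minimised/varying concept atoms and role atoms can appear:
        the fixed part is pinned).  Any future countermodel that
        (a) agrees with the current one on every atom sharing an axiom
        instance with a delta atom and (b) keeps the dropped minimised
        atoms true, admits the very same repair — overwrite its delta
        atoms with the preferred model's values: each axiom instance
        either avoids delta entirely or evaluates exactly as in the
        preferred model, and the result sits strictly below.  One clause
        blocks the whole family.
        """
        delta = {v for v, val in m_vals.items() if p_vals[v] != val}
        support: set = set()
        for atoms in self.chunks:
            if atoms & delta:
                support |= atoms - delta
        dropped = False
        clause = [-self.act]
        for v in sorted(support):
            if self._classes.get(v, "skip") == "skip":
                continue
            clause.append(-v if m_vals.get(v) else v)
        for v in sorted(delta):
            if self._classes[v] == "min" and m_vals[v]:
                clause.append(-v)
                if not p_vals[v]:
                    dropped = True
        assert dropped, "strictly preferred model without a dropped atom"
        self.solver.add_clause(clause)


def circ_entails(ontology: Ontology, spec: CircumscriptionSpec, goal,
                 bound: int, engine: str = "ground",
                 so_bound: int = 8) -> BoundedVerdict:
    """Does every minimal model within the bound satisfy the goal?

    ``refuted`` returns a *minimal* countermodel.  With an empty minimised
    set this coincides with classical bounded entailment, and every
    classically entailed goal is circumscriptively entailed
    (minimal models are models).
    """
    axioms = list(ontology.axioms)
    _check_bound(axioms, bound)
    sig = _signature_with(ontology, goal)

    classical = entails(ontology, goal, bound, engine=engine,
                        so_bound=so_bound)
    if classical.status in ("holds_up_to_bound", "inconsistent_premises"):
        return classical
    if spec.is_classical:
        return classical

    if engine == "enumerate":
        for n in range(1, bound + 1):
            models = list(enumerate_models(axioms, sig, n, so_bound))
            for m in models:
                if satisfies(m, goal, so_bound):
                    continue
                if not any(strictly_preferred(other, m, spec)
                           for other in models):
                    return BoundedVerdict("refuted", bound, witness=m,
                                          goal=goal)
        return BoundedVerdict("holds_up_to_bound", bound, goal=goal)

    for n in range(1, bound + 1):
        search = _CircSearch(axioms, sig, spec, goal, n, so_bound)
        witness = search.run()
        if witness is not None:
            return BoundedVerdict("refuted", bound, witness=witness,
                                  goal=goal)
    return BoundedVerdict("holds_up_to_bound", bound, goal=goal)
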