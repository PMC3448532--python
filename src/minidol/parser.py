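"""Parser for the ``.mdol`` dialect.

One line-oriented, whitespace-tokenised dialect covers all logics in the
tower: ``props``/formula axioms for propositional modules, Manchester-style
frames (``Class``, ``ObjectProperty``, ``Individual``) for the description
logics, infix first-order formulas, and CLIF-style s-expressions for the
second-order fragment.  Documents may hold several modules plus
``interpretation`` links and circumscription blocks
(``minimise`` / ``vary`` / ``then %implies``).

Identifiers are normalised case-insensitively to the first-seen casing
(the source listings this dialect transcribes drift between e.g.
``isPartOf`` and ``ispartof``); a parser warning records each drift.
Unicode connectives are accepted and mapped to their keyword forms.
``+`` and ``-`` are ordinary identifier characters, so names such as
``HER2+_Cell`` and score individuals ``1+`` need no quoting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import core
from .core import (And, Asymmetric, Atomic, Bottom, ClassAssertion, Const,
                   DifferentFrom, DisjointClasses, DisjointUnion, Eq,
                   EquivalentClasses, ExistsI, ExistsP, ExtEq, Exactly, FAnd,
                   FIff, FImplies, FNot, FOr, ForallI, ForallP, Implies, Inv,
                   LogicId, Nominal, Not, Only, Ontology, Or, PredAtom,
                   PropAxiom, RoleAssertion, Signature, Some, SubClassOf,
                   SubPropertyChain, SubPropertyOf, Top, Transitive, Var)
from .errors import DialectSyntaxError, ExpressivityError

__all__ = ["parse_module", "parse_document_items", "parse_goal", "CircBlock"]

_UNICODE = {
    "⋁": "or", "∨": "or", "⋀": "and", "∧": "and", "→": "implies",
    "↔": "iff", "¬": "not", "⊥": "false", "⊤": "true", "∀": "forall",
    "∃": "exists", "∘": "o", "×": "x",
}

_KEYWORDS = {
    "logic", "ontology", "distributed-ontology", "then", "props", "class",
    "subclassof", "equivalentto", "disjointunionof", "disjointclasses",
    "objectproperty", "characteristics", "transitive", "asymmetric",
    "subpropertyof", "subpropertychain", "individual", "types", "facts",
    "differentfrom", "some", "only", "exactly", "inverse", "thing",
    "nothing", "and", "or", "not", "implies", "iff", "if", "false", "true",
    "forall", "exists", "interpretation", "with", "translation", "to",
    "minimise", "minimize", "vary", "%implies", "owl",
}

_LOGIC_NAMES = {
    "propositional": LogicId.PROP, "prop": LogicId.PROP,
    "el": LogicId.EL,
    "owl": LogicId.DL, "dl": LogicId.DL, "owl-dl": LogicId.DL,
    "expdl": LogicId.EXPDL,
    "fol": LogicId.FOL,
    "commonlogic": LogicId.CL, "cl": LogicId.CL,
}

_PUNCT = "(){}:,."


@dataclass
class Token:
    text: str
    line: int
    col: int

    @property
    def lower(self) -> str:
        return self.text.lower()


def tokenize(text: str) -> list:
    toks = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for u, repl in _UNICODE.items():
            line = line.replace(u, f" {repl} ")
        i, n = 0, len(line)
        while i < n:
            ch = line[i]
            if ch.isspace():
                i += 1
                continue
            if ch == "%":
                if line.startswith("%%", i):
                    break  # comment to end of line
                if line.startswith("%{", i):
                    end = line.find("}%", i)
                    if end < 0:
                        break  # annotation runs to end of line
                    i = end + 2
                    continue
                if line[i:i + 8].lower() == "%implies":
                    toks.append(Token("%implies", lineno, i + 1))
                    i += 8
                    continue
                raise DialectSyntaxError("stray '%'", lineno, i + 1)
            if ch in _PUNCT:
                toks.append(Token(ch, lineno, i + 1))
                i += 1
                continue
            j = i
            while j < n and not line[j].isspace() and line[j] not in _PUNCT \
                    and line[j] != "%":
                j += 1
            toks.append(Token(line[i:j], lineno, i + 1))
            i = j
    return toks


@dataclass
class CircBlock:
    """A circumscription block attached to a module."""

    minimised: tuple = ()
    varying: tuple = ()
    implied: list = field(default_factory=list)


class _Normalizer:
    """Case-insensitive identifier canonicalisation (first casing wins)."""

    def __init__(self):
        self.canon: dict = {}
        self.warnings: list = []

    def norm(self, name: str, tok: Optional[Token] = None) -> str:
        key = name.lower()
        if key not in self.canon:
            self.canon[key] = name
            return name
        canonical = self.canon[key]
        if canonical != name and tok is not None:
            w = (f"identifier {name!r} normalised to {canonical!r} "
                 f"(line {tok.line})")
            if w not in self.warnings:
                self.warnings.append(w)
        return canonical


class _Parser:
    def __init__(self, text: str, normalizer: Optional[_Normalizer] = None):
        self.toks = tokenize(text)
        self.pos = 0
        self.norm = normalizer or _Normalizer()

    # -- token plumbing ----------------------------------------------------
    def peek(self, ahead: int = 0) -> Optional[Token]:
        # commas act as whitespace
        i, seen = self.pos, 0
        while i < len(self.toks):
            if self.toks[i].text == ",":
                i += 1
                continue
            if seen == ahead:
                return self.toks[i]
            seen += 1
            i += 1
        return None

    def next(self) -> Token:
        while self.pos < len(self.toks) and self.toks[self.pos].text == ",":
            self.pos += 1
        if self.pos >= len(self.toks):
            last = self.toks[-1] if self.toks else Token("", 1, 1)
            raise DialectSyntaxError("unexpected end of input",
                                     last.line, last.col)
        tok = self.toks[self.pos]
        self.pos += 1
        return tok

    def at_kw(self, *kws: str) -> bool:
        t = self.peek()
        return t is not None and t.lower in kws

    def eat_kw(self, *kws: str) -> Token:
        t = self.next()
        if t.lower not in kws:
            raise DialectSyntaxError(
                f"expected {' or '.join(kws)!s}, found {t.text!r}",
                t.line, t.col)
        return t

    def skip_colon(self) -> None:
        if self.at_kw(":"):
            self.next()

    def name(self) -> str:
        t = self.next()
        if t.lower in _KEYWORDS or t.text in _PUNCT or t.text == "=":
            raise DialectSyntaxError(f"expected identifier, found {t.text!r}",
                                     t.line, t.col)
        return self.norm.norm(t.text, t)

    # -- entry points ------------------------------------------------------
    def parse_document_items(self) -> list:
        """Parse a document into ('module', Ontology, CircBlock|None) and
        ('interpretation', name, src, edge, tgt) items."""
        items = []
        doc_name = None
        if self.at_kw("distributed-ontology"):
            self.next()
            doc_name = self.name()
        while self.peek() is not None:
            if self.at_kw("logic"):
                ont, circ = self._parse_module_block()
                items.append(("module", ont, circ))
            elif self.at_kw("interpretation"):
                items.append(self._parse_interpretation())
            else:
                t = self.peek()
                raise DialectSyntaxError(
                    f"expected 'logic' or 'interpretation', found {t.text!r}",
                    t.line, t.col)
        return [("document", doc_name)] + items

    def parse_module(self) -> Ontology:
        if self.at_kw("distributed-ontology"):
            t = self.peek()
            raise DialectSyntaxError(
                "parse_module expects a single module, found a "
                "distributed-ontology document", t.line, t.col)
        ont, circ = self._parse_module_block()
        if self.peek() is not None:
            t = self.peek()
            raise DialectSyntaxError(
                f"trailing input after module: {t.text!r}", t.line, t.col)
        ont.circ_block = circ
        return ont

    # -- module ------------------------------------------------------------
    def _parse_module_block(self):
        self.eat_kw("logic")
        # optional label, e.g. "logic log : OWL"
        if self.peek(1) is not None and self.peek(1).text == ":":
            self.next()
            self.next()
        t = self.next()
        logic = _LOGIC_NAMES.get(t.lower)
        if logic is None:
            raise DialectSyntaxError(f"unknown logic {t.text!r}",
                                     t.line, t.col)
        self.eat_kw("ontology")
        name = self.name()
        self.eat_kw("=")
        imports = []
        # import list: Name [with translation Edge] (and ...)* then
        if not self._at_body_start():
            while True:
                imp = self.name()
                edge = None
                if self.at_kw("with"):
                    self.next()
                    self.eat_kw("translation")
                    edge = self.name()
                imports.append((imp, edge))
                if self.at_kw("and"):
                    self.next()
                    continue
                break
            self.eat_kw("then")
        braced = False
        if self.at_kw("{") and logic in (LogicId.FOL, LogicId.CL):
            # a braced body (CLIF listings wrap the axiom block in braces)
            nxt = self.peek(1)
            if nxt is not None and nxt.text == ".":
                braced = True
                self.next()

        ont = Ontology(name=name, logic=logic, imports=imports)
        self.sig = ont.signature
        self.logic = logic
        circ: Optional[CircBlock] = None
        while True:
            t = self.peek()
            if t is None or t.lower in ("logic", "ontology", "interpretation",
                                        "distributed-ontology"):
                break
            if braced and t.text == "}":
                self.next()
                break
            if t.lower in ("minimise", "minimize", "vary", "then"):
                circ = self._parse_circ_block(circ)
                continue
            before = t
            axioms = self._parse_frame()
            for ax in axioms:
                self._check_expressivity(ax, before)
                ont.axioms.append(ax)
        if self.norm.warnings:
            ont.annotations.setdefault(
                "parser_warnings", "; ".join(self.norm.warnings))
        ont.signature.validate()
        ont.circ_block = circ
        return ont, circ

    def _at_body_start(self) -> bool:
        t = self.peek()
        if t is None:
            return True
        return t.lower in ("props", "class", "objectproperty", "individual",
                           "minimise", "minimize", "vary", ".", "{",
                           "logic", "ontology", "interpretation")

    def _check_expressivity(self, ax, tok: Token) -> None:
        bad = core.forbidden_constructs(ax, self.logic)
        if bad:
            err = ExpressivityError(bad[0], self.logic.name)
            raise ExpressivityError(
                bad[0], f"{self.logic.name} (line {tok.line})") from err

    # -- circumscription block --------------------------------------------
    def _parse_circ_block(self, circ: Optional[CircBlock]) -> CircBlock:
        circ = circ or CircBlock()
        t = self.peek()
        if t.lower in ("minimise", "minimize"):
            self.next()
            circ.minimised = circ.minimised + tuple(self._name_list())
            return circ
        if t.lower == "vary":
            self.next()
            circ.varying = circ.varying + tuple(self._name_list())
            return circ
        # then %implies <frames>
        self.eat_kw("then")
        self.eat_kw("%implies")
        while True:
            t = self.peek()
            if t is None or t.lower in ("logic", "ontology", "interpretation",
                                        "distributed-ontology", "minimise",
                                        "minimize", "vary", "then"):
                break
            circ.implied.extend(self._parse_frame())
        return circ

    def _name_list(self) -> list:
        out = [self.name()]
        while True:
            t = self.peek()
            if t is None or t.lower in _KEYWORDS or t.text in _PUNCT:
                break
            out.append(self.name())
        # names in minimise/vary lists are concepts; undeclared ones are
        # auto-declared (with a warning) so the printed listings parse.
        for n in out:
            if n not in self.sig.concepts:
                self.sig.concepts.add(n)
                self.norm.warnings.append(
                    f"undeclared concept {n!r} in minimise/vary list "
                    f"auto-declared")
        return out

    # -- frames ------------------------------------------------------------
    def _parse_frame(self) -> list:
        t = self.peek()
        if t.lower == "props":
            self.next()
            self.skip_colon()
            for n in self._raw_name_list():
                self.sig.props.add(n)
            return []
        if t.text == ".":
            self.next()
            return [self._parse_axiom_formula()]
        if t.lower == "class":
            return self._parse_class_frame()
        if t.lower == "objectproperty":
            return self._parse_property_frame()
        if t.lower == "individual":
            return self._parse_individual_frame()
        raise DialectSyntaxError(f"unexpected token {t.text!r}",
                                 t.line, t.col)

    def _raw_name_list(self) -> list:
        out = [self.name()]
        while True:
            t = self.peek()
            if t is None or t.lower in _KEYWORDS or t.text in _PUNCT:
                break
            out.append(self.name())
        return out

    def _parse_class_frame(self) -> list:
        self.eat_kw("class")
        self.skip_colon()
        name = self.name()
        self.sig.concepts.add(name)
        axioms = []
        while True:
            t = self.peek()
            if t is None:
                break
            if t.lower == "subclassof":
                self.next()
                self.skip_colon()
                axioms.append(SubClassOf(Atomic(name), self._concept()))
            elif t.lower == "equivalentto":
                self.next()
                self.skip_colon()
                axioms.append(EquivalentClasses(Atomic(name), self._concept()))
            elif t.lower == "disjointunionof":
                self.next()
                self.skip_colon()
                parts = tuple(self._concept_list())
                axioms.append(DisjointUnion(name, parts))
            elif t.lower == "disjointclasses":
                self.next()
                self.skip_colon()
                parts = (Atomic(name),) + tuple(self._concept_list())
                axioms.append(DisjointClasses(parts))
            else:
                break
        return axioms

    def _parse_property_frame(self) -> list:
        self.eat_kw("objectproperty")
        self.skip_colon()
        name = self.name()
        self.sig.roles.add(name)
        axioms = []
        while True:
            t = self.peek()
            if t is None:
                break
            if t.lower == "characteristics":
                self.next()
                self.skip_colon()
                while self.at_kw("transitive", "asymmetric"):
                    k = self.next()
                    axioms.append(Transitive(name) if k.lower == "transitive"
                                  else Asymmetric(name))
            elif t.lower == "subpropertyof":
                self.next()
                self.skip_colon()
                sup = self.name()
                self.sig.roles.add(sup)
                axioms.append(SubPropertyOf(name, sup))
            elif t.lower == "subpropertychain":
                self.next()
                self.skip_colon()
                chain = [self.name()]
                while self.peek() is not None and self.peek().lower == "o":
                    self.next()
                    chain.append(self.name())
                for r in chain:
                    self.sig.roles.add(r)
                axioms.append(SubPropertyChain(tuple(chain), name))
            else:
                break
        return axioms

    def _parse_individual_frame(self) -> list:
        self.eat_kw("individual")
        self.skip_colon()
        name = self.name()
        self.sig.individuals.add(name)
        axioms = []
        while True:
            t = self.peek()
            if t is None:
                break
            if t.lower == "types":
                self.next()
                self.skip_colon()
                for c in self._concept_list():
                    axioms.append(ClassAssertion(c, name))
            elif t.lower == "differentfrom":
                self.next()
                self.skip_colon()
                for other in self._raw_name_list():
                    self.sig.individuals.add(other)
                    axioms.append(DifferentFrom(name, other))
            elif t.lower == "facts":
                self.next()
                self.skip_colon()
                while True:
                    tt = self.peek()
                    if tt is None or tt.lower in _KEYWORDS or \
                            tt.text in _PUNCT:
                        break
                    role = self.name()
                    obj = self.name()
                    self.sig.roles.add(role)
                    self.sig.individuals.add(obj)
                    axioms.append(RoleAssertion(role, name, obj))
            else:
                break
        return axioms

    # -- concepts (Manchester-style) ----------------------------------------
    _frame_enders = ("class", "objectproperty", "individual", "logic",
                     "ontology", "interpretation", "distributed-ontology",
                     "subclassof", "equivalentto", "disjointunionof",
                     "disjointclasses", "types", "differentfrom", "facts",
                     "characteristics", "subpropertyof", "subpropertychain",
                     "minimise", "minimize", "vary", "then", ".", "%implies")

    def _concept_list(self) -> list:
        out = [self._concept()]
        while True:
            t = self.peek()
            if t is None or t.lower in self._frame_enders or t.text in ")}":
                break
            out.append(self._concept())
        return out

    def _concept(self):
        return self._concept_or()

    def _concept_or(self):
        parts = [self._concept_and()]
        while self.at_kw("or"):
            self.next()
            parts.append(self._concept_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def _concept_and(self):
        parts = [self._concept_prim()]
        while self.at_kw("and"):
            self.next()
            parts.append(self._concept_prim())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def _concept_prim(self):
        t = self.peek()
        if t is None:
            raise DialectSyntaxError("expected concept", 0, 0)
        if t.lower == "not":
            self.next()
            return Not(self._concept_prim())
        if t.lower == "thing":
            self.next()
            return Top()
        if t.lower == "nothing":
            self.next()
            return Bottom()
        if t.text == "(":
            self.next()
            c = self._concept()
            self.eat_kw(")")
            return c
        if t.text == "{":
            self.next()
            inds = []
            while not self.at_kw("}"):
                n = self.name()
                self.sig.individuals.add(n)
                inds.append(n)
            self.next()
            return Nominal(tuple(inds))
        if t.lower == "inverse":
            self.next()
            role = self.name()
            self.sig.roles.add(role)
            return self._restriction(Inv(role))
        # name: restriction head or atomic concept
        nxt = self.peek(1)
        if nxt is not None and nxt.lower in ("some", "only", "exactly"):
            role = self.name()
            self.sig.roles.add(role)
            return self._restriction(role)
        name = self.name()
        self.sig.concepts.add(name)
        return Atomic(name)

    def _restriction(self, role):
        t = self.next()
        if t.lower == "some":
            return Some(role, self._concept_prim())
        if t.lower == "only":
            return Only(role, self._concept_prim())
        if t.lower == "exactly":
            n = self.next()
            if not n.text.isdigit():
                raise DialectSyntaxError(
                    f"expected a number after 'Exactly', found {n.text!r}",
                    n.line, n.col)
            count = int(n.text)
            # optional qualified filler
            nt = self.peek()
            if nt is None or nt.lower in self._frame_enders or \
                    nt.lower in ("and", "or") or nt.text in ")}":
                filler = Top()
            else:
                filler = self._concept_prim()
            return Exactly(count, role, filler)
        raise DialectSyntaxError(f"expected restriction, found {t.text!r}",
                                 t.line, t.col)

    # -- dot-axioms: propositional, FOL infix, CLIF s-expressions ----------
    def _parse_axiom_formula(self):
        if self.logic == LogicId.PROP:
            return PropAxiom(self._prop_formula())
        if self.logic in (LogicId.EL, LogicId.DL, LogicId.EXPDL):
            # dot-axioms with complex left-hand sides
            if self.at_kw("disjointclasses"):
                self.next()
                self.skip_colon()
                return DisjointClasses(tuple(self._concept_list()))
            left = self._concept()
            kw = self.eat_kw("subclassof", "equivalentto")
            right = self._concept()
            return (SubClassOf(left, right) if kw.lower == "subclassof"
                    else EquivalentClasses(left, right))
        if self.at_kw("("):
            return self._clif_formula()
        return self._fol_formula(bound=set())

    # propositional, lowest precedence: implies (right-assoc) < or < and < not
    def _prop_formula(self):
        left = self._prop_or()
        if self.at_kw("implies"):
            self.next()
            return Implies(left, self._prop_formula())
        return left

    def _prop_or(self):
        parts = [self._prop_and()]
        while self.at_kw("or"):
            self.next()
            parts.append(self._prop_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def _prop_and(self):
        parts = [self._prop_atom()]
        while self.at_kw("and"):
            self.next()
            parts.append(self._prop_atom())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def _prop_atom(self):
        t = self.peek()
        if t.lower == "not":
            self.next()
            return Not(self._prop_atom())
        if t.lower == "false":
            self.next()
            return Bottom()
        if t.lower == "true":
            self.next()
            return Top()
        if t.text == "(":
            self.next()
            f = self._prop_formula()
            self.eat_kw(")")
            return f
        name = self.name()
        self.sig.props.add(name)
        return Atomic(name)

    # infix FOL: iff < implies < or < and < not/quantifier/atom
    def _fol_formula(self, bound: set):
        left = self._fol_implies(bound)
        while self.at_kw("iff"):
            self.next()
            left = FIff(left, self._fol_implies(bound))
        return left

    def _fol_implies(self, bound: set):
        left = self._fol_or(bound)
        if self.at_kw("implies"):
            self.next()
            return FImplies(left, self._fol_implies(bound))
        return left

    def _fol_or(self, bound: set):
        parts = [self._fol_and(bound)]
        while self.at_kw("or"):
            self.next()
            parts.append(self._fol_and(bound))
        return parts[0] if len(parts) == 1 else FOr(tuple(parts))

    def _fol_and(self, bound: set):
        parts = [self._fol_unit(bound)]
        while self.at_kw("and"):
            self.next()
            parts.append(self._fol_unit(bound))
        return parts[0] if len(parts) == 1 else FAnd(tuple(parts))

    def _fol_unit(self, bound: set):
        t = self.peek()
        if t.lower == "not":
            self.next()
            return FNot(self._fol_unit(bound))
        if t.lower == "true":
            self.next()
            return FAnd(())
        if t.lower == "false":
            self.next()
            return FOr(())
        if t.lower in ("forall", "exists"):
            kw = self.next().lower
            vars_ = []
            while self.peek() is not None and self.peek().text != "(" and \
                    self.peek().lower not in _KEYWORDS:
                vars_.append(self.next().text)
            body = self._fol_unit(bound | set(vars_))
            node = ForallI if kw == "forall" else ExistsI
            return node(tuple(vars_), body)
        if t.text == "(":
            self.next()
            f = self._fol_formula(bound)
            self.eat_kw(")")
            return f
        # atom: Pred ( t1 ... tn ) or equality: t1 = t2
        nxt = self.peek(1)
        if nxt is not None and nxt.text == "=":
            left = self._fol_term(bound)
            self.next()  # '='
            return Eq(left, self._fol_term(bound))
        pred = self.name()
        self.eat_kw("(")
        args = []
        while not self.at_kw(")"):
            args.append(self._fol_term(bound))
        self.next()
        self.sig.predicates.add((pred, len(args)))
        return PredAtom(pred, tuple(args))

    def _fol_term(self, bound: set):
        t = self.next()
        if t.text in bound:
            return Var(t.text)
        name = self.norm.norm(t.text, t)
        self.sig.individuals.add(name)
        return Const(name)

    # CLIF s-expressions -----------------------------------------------------
    def _clif_formula(self):
        sexpr = self._read_sexpr()
        pred_vars: set = set()
        return self._convert_sexpr(sexpr, {}, pred_vars)

    def _read_sexpr(self):
        t = self.next()
        if t.text != "(":
            return t
        out = []
        while True:
            nt = self.peek()
            if nt is None:
                raise DialectSyntaxError("unbalanced '('", t.line, t.col)
            if nt.text == ")":
                self.next()
                return out
            out.append(self._read_sexpr())

    @staticmethod
    def _pred_positions(sexpr, acc: set):
        """Names used in operator position anywhere in a raw s-expression."""
        if isinstance(sexpr, list) and sexpr:
            head = sexpr[0]
            if isinstance(head, Token) and head.lower not in (
                    "forall", "exists", "and", "or", "not", "if", "iff", "="):
                acc.add(head.text)
            for child in sexpr:
                _Parser._pred_positions(child, acc)

    def _convert_sexpr(self, sx, env: dict, _unused):
        # env: var name -> "ind" | "pred"
        if not isinstance(sx, list):
            raise DialectSyntaxError("expected an s-expression",
                                     sx.line, sx.col)
        if not sx:
            raise DialectSyntaxError("empty s-expression", 0, 0)
        head = sx[0]
        if not isinstance(head, Token):
            raise DialectSyntaxError("s-expression head must be a symbol",
                                     0, 0)
        hl = head.lower
        if hl in ("forall", "exists"):
            if len(sx) != 3 or not isinstance(sx[1], list):
                raise DialectSyntaxError(
                    "quantifier needs a variable list and a body",
                    head.line, head.col)
            var_toks = sx[1]
            op_pos: set = set()
            self._pred_positions(sx[2], op_pos)
            ivars, pvars = [], []
            for vt in var_toks:
                if vt.text in op_pos or self._eq_with_pred(sx[2], vt.text):
                    pvars.append(vt.text)
                else:
                    ivars.append(vt.text)
            env2 = dict(env)
            env2.update({v: "ind" for v in ivars})
            env2.update({v: "pred" for v in pvars})
            body = self._convert_sexpr(sx[2], env2, None)
            if pvars and ivars:
                inner = (ForallI if hl == "forall" else ExistsI)(
                    tuple(ivars), body)
                return (ForallP if hl == "forall" else ExistsP)(
                    tuple(pvars), inner)
            if pvars:
                return (ForallP if hl == "forall" else ExistsP)(
                    tuple(pvars), body)
            return (ForallI if hl == "forall" else ExistsI)(
                tuple(ivars), body)
        if hl == "and":
            return FAnd(tuple(self._convert_sexpr(c, env, None)
                              for c in sx[1:]))
        if hl == "or":
            return FOr(tuple(self._convert_sexpr(c, env, None)
                             for c in sx[1:]))
        if hl == "not":
            return FNot(self._convert_sexpr(sx[1], env, None))
        if hl == "if":
            return FImplies(self._convert_sexpr(sx[1], env, None),
                            self._convert_sexpr(sx[2], env, None))
        if hl == "iff":
            return FIff(self._convert_sexpr(sx[1], env, None),
                        self._convert_sexpr(sx[2], env, None))
        if hl == "=":
            a, b = sx[1], sx[2]
            if not isinstance(a, Token) or not isinstance(b, Token):
                raise DialectSyntaxError("'=' expects two symbols",
                                         head.line, head.col)
            if env.get(a.text) == "pred" or env.get(b.text) == "pred":
                var, pred = (a, b) if env.get(a.text) == "pred" else (b, a)
                pname = self.norm.norm(pred.text, pred)
                self.sig.predicates.add((pname, 1))
                return ExtEq(var.text, pname)
            return Eq(self._clif_term(a, env), self._clif_term(b, env))
        # application
        if env.get(head.text) == "pred":
            pred = Var(head.text)
        else:
            pred = self.norm.norm(head.text, head)
            self.sig.predicates.add((pred, len(sx) - 1))
        args = tuple(self._clif_term(a, env) for a in sx[1:])
        return PredAtom(pred, args)

    @staticmethod
    def _eq_with_pred(sexpr, var: str) -> bool:
        if isinstance(sexpr, list):
            if (len(sexpr) == 3 and isinstance(sexpr[0], Token)
                    and sexpr[0].lower == "=" and isinstance(sexpr[1], Token)
                    and isinstance(sexpr[2], Token)):
                a, b = sexpr[1].text, sexpr[2].text
                if var in (a, b):
                    other = b if a == var else a
                    # an '=' against a capitalised non-variable symbol is an
                    # extension comparison
                    return other[0].isupper() and other != var
            return any(_Parser._eq_with_pred(c, var) for c in sexpr)
        return False

    def _clif_term(self, tok, env: dict):
        if isinstance(tok, list):
            raise DialectSyntaxError("nested terms are not supported", 0, 0)
        if env.get(tok.text) == "ind":
            return Var(tok.text)
        if env.get(tok.text) == "pred":
            return Var(tok.text)
        name = self.norm.norm(tok.text, tok)
        self.sig.individuals.add(name)
        return Const(name)

    # -- interpretation links ----------------------------------------------
    def _parse_interpretation(self):
        self.eat_kw("interpretation")
        name = self.name()
        self.eat_kw(":")
        src = self.name()
        self.eat_kw("with")
        self.eat_kw("translation")
        edge = self.name()
        self.eat_kw("to")
        tgt = self.name()
        return ("interpretation", name, src, edge, tgt)


def parse_module(text: str) -> Ontology:
    """Parse a single-module source into an :class:`~minidol.core.Ontology`.

    The text must declare exactly one ``logic`` and one ``ontology`` block;
    imports are recorded by name for later linking.  Syntax errors carry
    line/column; constructs outside the declared logic raise
    :class:`~minidol.errors.ExpressivityError`.
    """
    return _Parser(text).parse_module()


def parse_document_items(text: str, normalizer=None) -> list:
    """Low-level document parse used by :func:`minidol.dol.parse_distributed`."""
    return _Parser(text, normalizer).parse_document_items()


def parse_goal(text: str, logic: LogicId, signature: Signature):
    """Parse a single goal axiom for entailment queries.

    Accepts an ``Individual``/``Class`` frame, a dot-axiom (``. <formula>``)
    or a bare subsumption ``<concept> SubClassOf <concept>``.
    """
    p = _Parser(text)
    p.sig = Signature(set(signature.concepts), set(signature.roles),
                      set(signature.individuals), set(signature.props),
                      set(signature.predicates))
    # seed the normalizer with the signature's canonical casings
    for n in p.sig.all_names():
        p.norm.canon.setdefault(n.lower(), n)
    p.logic = logic
    t = p.peek()
    if t is None:
        raise DialectSyntaxError("empty goal", 1, 1)
    if t.lower in ("individual", "class", "objectproperty"):
        axioms = p._parse_frame()
    elif t.text == ".":
        p.next()
        axioms = [p._parse_axiom_formula()]
    else:
        left = p._concept()
        kw = p.eat_kw("subclassof", "equivalentto")
        right = p._concept()
        axioms = [SubClassOf(left, right) if kw.lower == "subclassof"
                  else EquivalentClasses(left, right)]
    if len(axioms) != 1:
        return FAnd(tuple(axioms)) if logic >= LogicId.FOL else axioms
    return axioms[0]
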