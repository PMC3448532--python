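"""Canonical pretty-printer and JSON serialisation.

``module_to_text`` emits dialect source that re-parses to an equal module
(up to axiom order); atomic-subject axioms print as Manchester-style
frames, everything else as dot-axioms.  First-order axioms print infix;
axioms using second-order quantification print as CLIF s-expressions.
"""

from __future__ import annotations

from .core import (And, Asymmetric, Atomic, Bottom, ClassAssertion,
                   DifferentFrom, DisjointClasses, DisjointUnion, Eq,
                   EquivalentClasses, Exactly, ExistsI, ExistsP, ExtEq, FAnd,
                   FIff, FImplies, FNot, FOr, ForallI, ForallP, Implies, Inv,
                   LogicId, Nominal, Not, Only, Ontology, Or, PredAtom,
                   PropAxiom, RoleAssertion, SO_NODES, Some, SubClassOf,
                   SubPropertyChain, SubPropertyOf, Top, Transitive, Var)

__all__ = ["concept_to_text", "axiom_to_text", "module_to_text",
           "document_to_text", "ontology_to_dict"]

_LOGIC_TEXT = {
    LogicId.PROP: "Propositional", LogicId.EL: "EL", LogicId.DL: "OWL",
    LogicId.EXPDL: "ExpDL", LogicId.FOL: "FOL", LogicId.CL: "CommonLogic",
}


def _role_text(role) -> str:
    if isinstance(role, Inv):
        return f"inverse {role.role}"
    return role


def concept_to_text(c) -> str:
    if isinstance(c, Top):
        return "Thing"
    if isinstance(c, Bottom):
        return "Nothing"
    if isinstance(c, Atomic):
        return c.name
    if isinstance(c, Not):
        return f"( Not {concept_to_text(c.arg)} )"
    if isinstance(c, And):
        return "( " + " And ".join(concept_to_text(a) for a in c.args) + " )"
    if isinstance(c, Or):
        return "( " + " Or ".join(concept_to_text(a) for a in c.args) + " )"
    if isinstance(c, Implies):
        return (f"( {concept_to_text(c.left)} implies "
                f"{concept_to_text(c.right)} )")
    if isinstance(c, Some):
        return f"( {_role_text(c.role)} Some {concept_to_text(c.filler)} )"
    if isinstance(c, Only):
        return f"( {_role_text(c.role)} Only {concept_to_text(c.filler)} )"
    if isinstance(c, Exactly):
        return (f"( {_role_text(c.role)} Exactly {c.n} "
                f"{concept_to_text(c.filler)} )")
    if isinstance(c, Nominal):
        return "{ " + " ".join(c.individuals) + " }"
    raise TypeError(f"not a concept: {c!r}")


def _term_text(t) -> str:
    return t.name


def fol_to_text(f) -> str:
    if isinstance(f, PredAtom):
        args = " ".join(_term_text(a) for a in f.args)
        return f"{f.pred} ( {args} )"
    if isinstance(f, Eq):
        return f"( {_term_text(f.left)} = {_term_text(f.right)} )"
    if isinstance(f, FNot):
        return f"( not {fol_to_text(f.arg)} )"
    if isinstance(f, FAnd):
        if not f.args:
            return "true"
        return "( " + " and ".join(fol_to_text(a) for a in f.args) + " )"
    if isinstance(f, FOr):
        if not f.args:
            return "false"
        return "( " + " or ".join(fol_to_text(a) for a in f.args) + " )"
    if isinstance(f, FImplies):
        return f"( {fol_to_text(f.left)} implies {fol_to_text(f.right)} )"
    if isinstance(f, FIff):
        return f"( {fol_to_text(f.left)} iff {fol_to_text(f.right)} )"
    if isinstance(f, ForallI):
        return f"forall {' '.join(f.vars)} ( {fol_to_text(f.body)} )"
    if isinstance(f, ExistsI):
        return f"exists {' '.join(f.vars)} ( {fol_to_text(f.body)} )"
    raise TypeError(f"cannot print {f!r} infix (second-order?)")


def clif_to_text(f) -> str:
    if isinstance(f, PredAtom):
        head = f.pred.name if isinstance(f.pred, Var) else f.pred
        parts = [head]
        for a in f.args:
            parts.append(a.name)
        return "( " + " ".join(parts) + " )"
    if isinstance(f, Eq):
        return f"( = {f.left.name} {f.right.name} )"
    if isinstance(f, ExtEq):
        return f"( = {f.var} {f.pred} )"
    if isinstance(f, FNot):
        return f"( not {clif_to_text(f.arg)} )"
    if isinstance(f, FAnd):
        return "( and " + " ".join(clif_to_text(a) for a in f.args) + " )"
    if isinstance(f, FOr):
        return "( or " + " ".join(clif_to_text(a) for a in f.args) + " )"
    if isinstance(f, FImplies):
        return f"( if {clif_to_text(f.left)} {clif_to_text(f.right)} )"
    if isinstance(f, FIff):
        return f"( iff {clif_to_text(f.left)} {clif_to_text(f.right)} )"
    if isinstance(f, (ForallI, ForallP)):
        return (f"( forall ( {' '.join(f.vars)} ) "
                f"{clif_to_text(f.body)} )")
    if isinstance(f, (ExistsI, ExistsP)):
        return (f"( exists ( {' '.join(f.vars)} ) "
                f"{clif_to_text(f.body)} )")
    raise TypeError(f"not a first/second-order formula: {f!r}")


def _prop_text(f) -> str:
    if isinstance(f, Atomic):
        return f.name
    if isinstance(f, Top):
        return "true"
    if isinstance(f, Bottom):
        return "false"
    if isinstance(f, Not):
        return f"( not {_prop_text(f.arg)} )"
    if isinstance(f, And):
        return "( " + " and ".join(_prop_text(a) for a in f.args) + " )"
    if isinstance(f, Or):
        return "( " + " or ".join(_prop_text(a) for a in f.args) + " )"
    if isinstance(f, Implies):
        return f"( {_prop_text(f.left)} implies {_prop_text(f.right)} )"
    raise TypeError(f"not a propositional formula: {f!r}")


def _has_so(f) -> bool:
    if isinstance(f, SO_NODES):
        return True
    for attr in ("arg", "left", "right", "body"):
        ch = getattr(f, attr, None)
        if ch is not None and not isinstance(ch, (str, int, tuple)):
            if _has_so(ch):
                return True
    args = getattr(f, "args", None)
    if isinstance(args, tuple):
        for a in args:
            if not isinstance(a, (str, int)) and _has_so(a):
                return True
    return False


def axiom_to_text(ax, logic: LogicId) -> str:
    """One axiom as a dialect line (frame or dot-axiom)."""
    if isinstance(ax, PropAxiom):
        return f". {_prop_text(ax.formula)}"
    if isinstance(ax, SubClassOf):
        if isinstance(ax.sub, Atomic):
            return (f"Class {ax.sub.name} SubClassOf "
                    f"{concept_to_text(ax.sup)}")
        return (f". {concept_to_text(ax.sub)} SubClassOf "
                f"{concept_to_text(ax.sup)}")
    if isinstance(ax, EquivalentClasses):
        if isinstance(ax.left, Atomic):
            return (f"Class {ax.left.name} EquivalentTo "
                    f"{concept_to_text(ax.right)}")
        return (f". {concept_to_text(ax.left)} EquivalentTo "
                f"{concept_to_text(ax.right)}")
    if isinstance(ax, DisjointUnion):
        parts = " , ".join(concept_to_text(p) for p in ax.parts)
        return f"Class {ax.name} DisjointUnionOf {parts}"
    if isinstance(ax, DisjointClasses):
        parts = " , ".join(concept_to_text(p) for p in ax.parts)
        return f". DisjointClasses {parts}"
    if isinstance(ax, Transitive):
        return f"ObjectProperty {ax.role} Characteristics Transitive"
    if isinstance(ax, Asymmetric):
        return f"ObjectProperty {ax.role} Characteristics Asymmetric"
    if isinstance(ax, SubPropertyOf):
        return f"ObjectProperty {ax.sub} SubPropertyOf {ax.sup}"
    if isinstance(ax, SubPropertyChain):
        chain = " o ".join(ax.chain)
        return f"ObjectProperty {ax.sup} SubPropertyChain {chain}"
    if isinstance(ax, ClassAssertion):
        return (f"Individual {ax.individual} Types "
                f"{concept_to_text(ax.concept)}")
    if isinstance(ax, RoleAssertion):
        return f"Individual {ax.subject} Facts {ax.role} {ax.object}"
    if isinstance(ax, DifferentFrom):
        return f"Individual {ax.a} DifferentFrom {ax.b}"
    # first-/second-order
    if logic == LogicId.CL or _has_so(ax):
        return f". {clif_to_text(ax)}"
    return f". {fol_to_text(ax)}"


def module_to_text(ont: Ontology) -> str:
    """Canonical dialect source for one module (stable ordering)."""
    lines = [f"logic {_LOGIC_TEXT[ont.logic]}"]
    header = f"ontology {ont.name} ="
    if ont.imports:
        imps = []
        for imp, edge in ont.imports:
            imps.append(f"{imp} with translation {edge}" if edge else imp)
        header += " " + " and ".join(imps) + " then"
    lines.append(header)
    if ont.signature.props:
        lines.append("  props " + " , ".join(sorted(ont.signature.props)))
    for c in sorted(ont.signature.concepts):
        lines.append(f"  Class {c}")
    for r in sorted(ont.signature.roles):
        lines.append(f"  ObjectProperty {r}")
    for i in sorted(ont.signature.individuals):
        lines.append(f"  Individual {i}")
    for ax in ont.axioms:
        lines.append("  " + axiom_to_text(ax, ont.logic))
    circ = ont.circ_block
    if circ is not None:
        if circ.minimised:
            lines.append("  minimise " + " , ".join(circ.minimised))
        if circ.varying:
            lines.append("  vary " + " , ".join(circ.varying))
        if circ.implied:
            lines.append("  then %implies")
            for ax in circ.implied:
                lines.append("  " + axiom_to_text(ax, ont.logic))
    return "\n".join(lines) + "\n"


def document_to_text(doc) -> str:
    parts = []
    if doc.name:
        parts.append(f"distributed-ontology {doc.name}\n")
    for name in doc.modules:
        parts.append(module_to_text(doc.modules[name]))
    from .dol import InterpretationLink
    for link in doc.links:
        if isinstance(link, InterpretationLink):
            parts.append(f"interpretation {link.name} : {link.source} "
                         f"with translation {link.edge} to {link.target}\n")
    return "\n".join(parts)


def ontology_to_dict(ont: Ontology) -> dict:
    """JSON-ready form: signature by category, axioms as canonical dialect
    text (each line re-parses against the signature)."""
    return {
        "name": ont.name,
        "logic": ont.logic.name,
        "signature": ont.signature.to_dict(),
        "axioms": [axiom_to_text(ax, ont.logic) for ax in ont.axioms],
        "imports": [list(i) for i in ont.imports],
        "annotations": dict(ont.annotations),
    }
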