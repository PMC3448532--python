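# minidol

A desk-scale toolkit for **heterogeneous ontologies**: modules written in
logics of different expressivity, linked by translations and
interpretations, reasoned about over bounded finite domains, and extended
non-monotonically with circumscription.

Biomedical ontologies mix representation levels.  A terminology may need
nothing beyond propositional disjointness; a large anatomy ontology wants
the tractable EL profile; parthood ("every part of a part of x is a part
of x", "nothing is a proper part of itself") already pushes past OWL into
first- and second-order territory; and phenotype modelling needs
*defaults* — a tissue sample counts as normal until evidence of marker
overexpression arrives, which no monotonic logic can express directly.
Rather than forcing everything into one language, this package keeps each
module in its own logic and makes the connections formal objects.

## What's inside

* **A tower of logics** `PROP < EL < DL < EXPDL < FOL < CL` with one
  line-oriented dialect (`.mdol`) covering Manchester-style class frames,
  propositional and infix first-order axioms, and CLIF-style
  s-expressions with quantification over unary predicates.
* **A translation graph**: Prop→DL renders an implication φ → ψ as the
  subsumption τ(φ) ⊑ τ(ψ); DL→FOL is the standard relational translation
  (concepts to unary predicates, restrictions to guarded quantifiers);
  EL→DL, DL→ExpDL and FOL→CL are inclusions.  *Interpretation* links are
  verified model-theoretically: every translated source axiom must be
  entailed by the target, both lifted to their common supralogic.
* **Bounded finite-model reasoning.**  Consistency, entailment and
  classification are decided over all domains of size ≤ k (default
  k = 6); refutations return a concrete countermodel, verified against
  Tarskian satisfaction before it is reported.  Two engines: a
  backtracking model enumerator (the transparent oracle) and a grounding
  engine that compiles axioms — including finitely expanded second-order
  quantifiers — to CNF for a built-in CDCL SAT solver.
* **Parallel predicate circumscription.**  A specification
  `minimise M₁ … / vary V₁ …` induces a pre-order on models: I ⪯ J iff
  both agree on the domain, the individual denotations and every fixed
  concept, and ext_I(Mᵢ) ⊆ ext_J(Mᵢ) for all minimised concepts (roles
  and varying concepts move freely).  `circ_entails` decides whether
  every ⪯-minimal model satisfies a goal, by a counterexample-guided
  search that certifies minimal countermodels.
* **Two executable case studies**, shipped as `.mdol` fixtures:
  * a six-module **mereology tower** (propositional taxonomy of DOLCE-style
    categories, EL parthood, OWL proper parthood, an
    expressivity-exceeding DL module that makes a role both transitive
    and asymmetric, first-order overlap, and a Common Logic module with
    category guards, sums and fusion), plus the interpretation link from
    the taxonomy into the EL module;
  * a **HER2 breast-phenotype ontology**: immunohistochemistry scores
    0/1+/2+/3+ as nominal individuals (a qualitative abstraction of the
    >30 % staining threshold for HER2 positivity), disjoint
    normal/HER2-positive partitions of cell and tissue, a measured tissue
    individual X (score 3+), an unmeasured individual Y, and a
    circumscription block that minimises the HER2-positive ("abnormal")
    concepts so that unmeasured tissue *defaults* to normal.

## Worked example

```bash
$ minidol fixtures emit her2_reconciled > her2.mdol
$ minidol classify her2.mdol --bound 6
...
HER2_Positive SubClassOf IHC_HER2_Score
Normal_Tissue SubClassOf Tissue
X : HER2+_Tissue, Tissue
Y : Tissue
$ minidol circumscribe her2.mdol --bound 6
HER2#implies0: holds_up_to_bound
HER2#implies1: holds_up_to_bound
```

The classical classification types X — asserted to have IHC score 3+ —
as `HER2+_Tissue`, but says nothing about the unmeasured Y beyond
`Tissue`.  Under circumscription both printed obligations are derived:
X is HER2-positive tissue, and Y is `Normal_Tissue` with a score in
`HER2_Negative ⊔ HER2_Borderline` — the default.  Adding the assertion
`Y : hasHER2Score some {3+}` and re-running retracts Y's normality
(`refuted`, with a minimal countermodel printed): the defining
non-monotonic behaviour.

The same library surface is available programmatically:

```python
from minidol import build_her2, flatten, circ_entails, parse_goal
doc = build_her2("reconciled")
her2 = flatten(doc, "HER2")
link = next(l for l in doc.links if hasattr(l, "spec"))
goal = parse_goal("Individual Y Types Normal_Tissue", her2.logic,
                  her2.signature)
print(circ_entails(her2, link.spec, goal, bound=6).status)
# holds_up_to_bound
```

## Caveat

Verdicts are **bounded**: "holds up to bound k" quantifies over finite
models with at most k domain elements, not over all models.  This is an
honest desk-scale contract — unrestricted circumscription is undecidable
even over weak description logics — and the fixtures' claims are stated
at their documented bounds (4 for the mereology tower, 6 for HER2).
See `docs/methods.md` for the semantics, the algorithms and the known
limitations.
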