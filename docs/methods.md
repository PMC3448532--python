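# Methods

This note records the semantics the toolkit implements, the algorithms
behind its verdicts, the choices made where the design was genuinely
open, and what the shipped fixtures and tests do and do not establish.

## The logic tower and the dialect

Modules are written in one of six logics, linearly ordered by
expressivity: propositional logic (`PROP`), the sub-Boolean EL fragment
(`EL`: conjunction, existential restriction, nominals; no negation,
union, universal restriction, cardinality, and no asymmetric roles), an
OWL-style description logic (`DL`), the same concept language with the
OWL regularity restrictions deliberately relaxed (`EXPDL`), first-order
logic with equality (`FOL`), and a Common Logic fragment adding
quantification over unary predicate variables (`CL`).

One unified dialect covers all of them.  The source listings this
package transcribes mix Manchester-style frames with CLIF s-expressions
and drift in identifier casing (`isPartOf` / `ispartof`,
`IHC_HER2_Score` / `IHC_Her2_Score`); the parser therefore normalises
identifiers case-insensitively to the first casing seen and records a
warning for each drift, rather than failing silently or multiplying
symbols.  `+` and `-` are ordinary identifier characters so that names
like `HER2+_Cell` and the score individuals `1+`, `2+`, `3+` need no
quoting.  Unicode connectives (⋀, ⋁, →, ⊥, ∀, ∃) map to their keyword
forms.  Expressivity is enforced at parse time: using `Asymmetric` or a
Boolean constructor in an EL module is an error naming the construct and
the logic.

In CLIF s-expressions, a quantified variable is classified as a
*predicate* variable when it occurs in operator position inside its
scope or is compared by `=` against a unary predicate (extension
equality); mixed predicates such as `fusion`, whose first argument is a
predicate variable, are supported by letting extension tuples contain
sets of domain elements.

## Finite-model semantics

All reasoning is over finite interpretations: an explicit domain,
set-theoretic concept/role/predicate extensions, total individual
denotations and propositional valuations.  Satisfaction is classical
(Tarskian); qualified exact cardinality counts role successors in the
filler; `DifferentFrom(a,b)` holds iff the denotations differ (no
unique-name assumption otherwise); second-order quantifiers range over
all `2^|domain|` subsets and are refused beyond a configurable domain
size (`so_bound`, default 8) — at these sizes the expansion is exact,
not an approximation.

A verdict of `holds_up_to_bound` at bound *k* means: no countermodel
exists over any domain of size 1..k.  It is deliberately *not* a claim
of unbounded entailment; refutations, by contrast, are absolute, and
always carry a countermodel that is re-verified against the satisfaction
relation before being returned.  Bounds default to 4 for the mereology
document and 6 for the HER2 document; these were chosen as the smallest
round sizes comfortably above each fixture's minimal-model size (the
HER2 ontology needs at least 3 elements for the pairwise-distinct score
individuals plus head-room for the two tissue individuals).

## The two engines

**Enumeration (the oracle).**  A backtracking enumerator assigns one
symbol's extension at a time (individuals, then propositions, then
unary, then binary extensions; subsets in order of increasing size) and
checks an axiom as soon as every symbol it mentions is assigned, pruning
the subtree on violation.  It applies no symmetry breaking and yields
every model, isomorphic copies included.  Its value is transparency: it
is short enough to audit, and the grounding engine is tested against it.

**Grounding (the fast path).**  Axioms are expanded over a fixed domain
`{0..n-1}` into Boolean formulas over ground atoms (concept membership,
role pairs, individual-denotation indicators with exactly-one
constraints, proposition values; second-order quantifiers expand over
subsets), Tseitin-transformed, and handed to a built-in CDCL SAT solver
(two watched literals, first-UIP clause learning, non-chronological
backjumping, activity-ordered branching with phase hints; learned
clauses are dropped or guard-conditioned at call boundaries because
assumptions participate in learning).  Since domain elements are
interchangeable a priori, individual denotations are restricted to
canonical value-precedence form (the j-th individual may use element d>0
only if an earlier one uses d−1); every interpretation is isomorphic to
exactly one canonical one, so existence, entailment and minimality
questions are unaffected.  The oracle never breaks symmetry.

Classification computes all bounded-entailed atomic subsumptions and
instance types.  Every model discovered along the way (consistency
witnesses, countermodels) prunes the remaining candidate pairs, so only
plausible subsumptions pay for a full entailment query; queries share
one grounding per domain size, with goals toggled through solver
assumptions.

## Translations and interpretation links

Sentence-level translations follow the edge path in the logic graph:
Prop→DL maps an implication φ → ψ to the subsumption τ(φ) ⊑ τ(ψ) and a
bare formula φ to ⊤ ⊑ τ(φ) (propositional valuations correspond to
per-element membership patterns, the reading under which the taxonomy
interpretation is true); DL→FOL is the standard relational translation,
with exact cardinality unfolded into at-least/at-most quantifier blocks
and nominals into equality disjunctions; EL→DL, DL→ExpDL and FOL→CL are
inclusions.  An *interpretation* link holds when every translated source
axiom is bounded-entailed by the target.  Because EL lacks full Boolean
negation, interpretation checking between propositional and EL modules
lifts both sides to DL first (the induced homogeneous interpretation);
in general both sides are lifted to their least common supralogic.
Interpretation links are checked for entailment only; whether such links
should additionally be model-expansive is left open, and an inconsistent
target is flagged on the verdict since entailment then trivialises.

Flattening a module resolves its `then` import closure, translating
every imported module into the least expressive logic of the tower that
admits all content (the maximum along the closure).  Combination
(`combine`) takes flattened ontologies plus an alignment: `synonym`
correspondences identify terms by renaming (strict identification —
the alignment's confidence value is recorded as an annotation and never
affects any verdict, a separation asserted by a differential test);
`subsumes` and `part_of` correspondences are added as axioms
(`A ⊑ B`, `A ⊑ ∃isPartOf.B`).

## Circumscription

The non-monotonic mechanism is parallel predicate circumscription as a
pre-order on finite models.  A specification partitions the concept
names into *minimised*, *varying* and (implicitly) *fixed*; I ⪯ J iff
the two models share their domain, individual denotations, propositional
valuation, n-ary predicate extensions and the extensions of every fixed
concept, and ext_I(M) ⊆ ext_J(M) for each minimised concept M.
`circ_entails` asks whether every ⪯-minimal model within the bound
satisfies the goal.

One semantic choice deserves emphasis: **role extensions vary** in the
pre-order.  If roles were frozen along with the fixed concepts, a model
in which the unmeasured tissue Y happens to carry a 3+ score edge would
be minimal within its own comparability class — the score assignment
could never be repaired — and no default conclusion about Y would ever
follow.  Minimising an abnormality concept must be allowed to re-route
*unasserted* role facts; asserted facts (X's 3+ score) are theorems in
every model and cannot be minimised away.  With this reading the HER2
defaults come out exactly as intended: every minimal model gives Y a
negative-or-borderline score and places it in `Normal_Tissue`, and
adding explicit evidence to the contrary retracts the default.

The decision procedure is counterexample-guided.  At each domain size:
find a model falsifying the goal; test its minimality by searching
(under the same clause store, with the fixed part pinned through
assumptions and a strictness clause) for a strictly preferred model,
biased by phase hints to stay close to the candidate so that repairs are
local; if none exists the candidate is a certified minimal countermodel.
Otherwise a clause is learned that excludes every countermodel to which
the same repair applies: the repair overwrites exactly the changed
atoms, so any model agreeing with the candidate on the atoms that share
a ground axiom instance with a changed atom (and on the dropped
minimised atoms) is also repaired by it, hence non-minimal.  Learning at
the granularity of ground axiom instances, rather than whole symbols,
is what keeps the clause from pinning unrelated parts of the structure;
on the HER2 document at bound 6 the search certifies the default in a
few dozen iterations.  Classically entailed goals short-circuit via
conservativity (minimal models are models).  An exhaustive
enumerate-filter-check path serves as the oracle for small instances,
and an empty minimised set provably coincides with classical entailment
(the strictness condition is unsatisfiable), which the tests assert on
seeded random instances.

Unrestricted circumscription is undecidable already over weak
description logics; the bounded-domain semantics sidesteps this
entirely — every question here is finite — at the price of the explicit
bound in every verdict.

## The fixtures and their irregularities

The fixtures transcribe printed listings, and the transcription policy
is: keep what is printed, reconcile only what cannot execute, and flag
every reconciliation.

* The propositional taxonomy's comment says the remaining disjointness
  axioms were "left out"; all six pairwise disjointness axioms among the
  categories S, T, AR, PD are generated.
* The dangling conjunct `hasHER2Score Exactly 1 IHC_HER2_Score` is
  attached to `Tissue` — the only reading consistent with the adjacent
  assumption that all tissue is IHC-measured.
* `HER2+_Cell_Membrane` is used but never declared in the source
  listing; the reconciled fixture declares it (and a matching
  `Normal_Cell_Membrane`) as subclasses of `Cell_Membrane`.
* The printed `vary` list names `Normal_Cancer_*` classes that match no
  declared class.  Both variants ship: `as_printed` keeps the names
  verbatim (auto-declared, with parser warnings), `reconciled` uses the
  declared `Normal_*` classes; a user-overridable mapping table
  (`VARY_RECONCILIATION`) converts one into the other.
* The Common Logic `sum` definition uses a conjunctive overlap condition
  and the `fusion` definition overlaps the set member with the fused
  entity where the classical forms use disjunction and the second
  argument; both the `as_printed` and the `classical` variants ship and
  neither is asserted to be the intended one.
* The mereology modules assert neither reflexivity nor antisymmetry of
  `isPartOf` — only what is printed.
* The HER2 document contains a single module that imports
  `ProperParthood`; the import resolves against the mereology document,
  attached as the parse *context* (unresolvable references without a
  context are errors).

## The random-module generator

Property tests (engine agreement, print/parse round-trips, translation
consistency-preservation) draw seeded random DL modules: up to 4 concept
names, 2 roles, 3 individuals and 10 axioms by default, with axioms
sampled over subsumptions between depth-≤2 concepts, disjointness, role
characteristics and ABox assertions.  The generator is deterministic per
seed.  These modules emulate the *shape* of small terminologies — they
are not distributionally faithful to any real ontology, so passing the
agreement suite shows engine correctness on the covered fragment, not
performance or adequacy on production-scale ontologies.

The engine-agreement suite runs the oracle at sizes it can exhaust:
200 instances capped at 3 concepts / 1 role / 2 individuals at bound 2,
plus 40 leaner instances at bound 3.  Exhaustive enumeration over the
generator's full default signature at bound 3 can reach ~10^10
interpretations on adversarial seeds, which is outside any reasonable
oracle budget; the grounding engine itself handles those sizes easily,
so the restriction concerns only the brute-force reference.

## Known limitations

* Bounded verdicts only; no tableau or consequence-based unbounded
  reasoning, and no claim of completeness for FOL/CL entailment.
* The enumeration engine does not support mixed second-order predicates
  (set-valued argument positions); the grounding engine does.
* OWL 2 datatypes, annotation semantics, punning, RDF/XML and
  functional-syntax I/O, and full CLIF conformance are out of scope; the
  dialect covers the fragments the case studies exercise.
* Alignments are inputs, never computed; there is no matching machinery
  and no conservative-extension checking.
* Percentages (the >30 % IHC threshold) are not modelled numerically;
  the score classes are the qualitative abstraction, by design.

## Serialisation

`Ontology.to_json` / `minidol.printer.ontology_to_dict` emit
`{name, logic, signature: {concepts, roles, individuals, props,
predicates}, axioms: [...], imports, annotations}` with axioms as
canonical dialect lines (each re-parses against the signature);
`FiniteInterpretation.to_dict` emits `{domain, concept_ext, role_ext,
pred_ext, indiv, prop_val}` with extensions as sorted lists, which is
the JSON form countermodels are printed in by the CLI.
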