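# Methods

## The knowledge model

`prockb` represents cellular metabolism process-first.  An *elementary*
biological process is characterised by its inputs and outputs and possibly
a mediator (an active molecular entity) and an activity; an *aggregated*
process (a pathway) is characterised by its subprocesses and their
ordering.  Molecule states are distinct individuals: an unmodified
complex, its carbamylated form and its metal-bound holoenzyme are three
individuals connected through the processes that transform them.  This is
what lets typing be state-specific — the holoenzyme, not the subunit,
carries the catalytic function.

The terminological layer is a 141-class DAG under three mutually disjoint
roots (`BiologicalProcess`, 65 classes, maximum subclass depth 7;
`Participant`, 48; `Activity`, 28) with 24 object properties (10 inverse
pairs; `has_input`/`has_output`/`mediated_by` under `has_participant`,
`starts_with`/`ends_with`/`has_intermediary_process` under
`has_subprocess`).  The high-level layer (disjoint splits
Chemical/Gene, GeneProduct/Non-geneProduct, Spontaneous/Mediated,
Metabolic/GeneProductModification, MolecularFunction/SpontaneousActivity)
is fixed by the model; classes below it are a reconstruction, and the
YAML config is deliberately the single source of truth so a different
class catalogue can be swapped in verbatim.  Imported classes keep their
original GO/ChEBI/NCI Thesaurus IRI in an `iri` field (exported verbatim
to RDF) while using readable ids internally — readable rule and table
files were judged worth the deviation from CURIEs-as-ids.

## Semantics of saturation

All entailment is positive, closed-world and materialising:

* **Schema entailments.** Subclass subsumption, sub-property propagation,
  inverse completion and domain/range typing are applied exhaustively.
  Domain/range axioms *type* rather than constrain — asserting
  `mediated_by(r, p)` makes `p` an `ActiveEntity`.
* **Rule catalog.** 27 safe Horn rules (conjunctive body and head, class
  and property atoms, `DifferentFrom` as id inequality under the
  unique-name assumption).  The distinct ids `ATP`, `ADP`, `P`, `Mg2+`
  are reserved with fixed typing because the ATP-dependent assembly rule
  names ADP and P as constants.
* **Defined classes.** Class definitions ("a mediated process has at
  least one mediator", "a metabolic process has only metabolites as
  inputs/outputs") are stored, but only their positive directions are
  realised, as rules (`mediated_by(r, ·) ⇒ MediatedProcess(r)`;
  metabolic inputs/outputs typed `Metabolite`).  Universal ("only")
  conditions are not inferred from — under open-world semantics they
  would require knowing a participant list is complete; routing the
  useful directions through rules side-steps that.
* **Pathway participants.** A dedicated pass (the exclusion is not
  expressible as a positive Horn rule): each pathway acquires
  `has_participant` to its subprocesses' inputs, outputs and mediators,
  minus every entity that is an output of one subprocess and an input of
  the immediately following subprocess along the declared `precedes`
  chain — transient intermediates are internal to the pathway.  The
  `precedes` edges within one pathway must form a chain; branching or
  cyclic orderings are structural errors (a biologically cyclic pathway
  is still represented, via its designated start and end).

Because rules are positive and no individuals are invented, the Herbrand
base is finite; saturation terminates at the unique least fixpoint, so
the result is monotone, idempotent and independent of rule or fact order.
Evaluation is semi-naive: every newly derived fact is joined once against
the store through each rule atom it can instantiate, with join order
chosen greedily by candidate-set size.  During saturation, class atoms
are evaluated against exact (materialised) membership — completeness
follows because each superclass membership arrives as its own fact and
re-triggers the rules — while the public `match_rule` evaluates class
atoms through the subsumption closure so it gives the same answers on
unsaturated stores.

Disjointness is the only consistency check: adding a class assertion that
clashes with an inherited disjointness raises an error naming both
classes and the provenances that derived them.  There is no tableau
reasoning, no negation-as-failure, no retraction.

## Counting conventions

Metrics report declared and inferred class/property assertion counts,
individuals and typing coverage.  Inferred counts exclude pairs already
declared (a declared assertion is never demoted, and re-deriving it does
not double-count) and include subsumption-propagated types.  Published
ontology-editor metrics are ambiguous about top-level membership, so
`exclude_roots` optionally drops root-class membership from the inferred
class count; the default counts it.

## Worked-example fixtures

The simple-enzyme fixture is deliberately minimal: one reaction described
by six property assertions (two inputs, two outputs, one mediator, one
activity) plus the Mg-ATP complexation subgraph (three individuals, three
assertions) without which the Mg-ATP decomposition has no source.  The
complex-enzyme fixture covers chaperoned assembly, covalent modification,
cofactor binding and two catalytic reactions, plus a three-step
activation pathway.  Two modelling choices matter here: the
function-assignment rule types its mediator variable `Participant` (the
mediator ranges over participants; a process-typed mediator would never
match), and the contribution rule reads "part of the function carrier
contributes to the function" with the part on the object side of
`has_molecular_part` — the only direction under which subunits contribute
to the holoenzyme's activity.  `ProteinComplexAssembly` is *not* a
subclass of `SpontaneousProcess` even though spontaneous assemblies
exist: chaperone-mediated assemblies would otherwise clash with the
inferred `MediatedProcess` typing; spontaneity is expressed per-instance
instead.

## The synthetic generator

`generate_network` emits the motifs the rules consume: enzymatic
metabolic reactions (1–2 fresh metabolite inputs/outputs, a
simple-protein mediator, an activity drawn from the seven catalytic
activity classes), protein complex assemblies (2–4 subunits by default; a
configurable fraction ATP-dependent, consuming ATP and producing ADP and
P), kinase-mediated protein phosphorylations, and precedes-ordered
pathways whose steps share chain metabolites (so each internal chain
metabolite is a transient intermediate) plus per-step cofactor inputs.
Defaults (24 metabolic reactions, 58 modifications, 10 assemblies, one
pathway) mirror a single curated pathway's composition.  Draws are
uniform from a seeded generator; identical parameters give byte-identical
tables.  Alongside the table the generator computes, constructively and
without running the engine, the exact set of assertions saturation must
add: per-motif rule consequences are enumerated directly and closed under
an independent naive schema-closure loop.  Tests require the saturated
store to equal this ledger in both directions.

What the generator does *not* emulate: stoichiometry, kinetics,
shared metabolites between unrelated reactions, enzymes mediating more
than one reaction, multi-level complexes-of-complexes, or inconsistent
curation.  Passing tests therefore demonstrate the correctness of the
inference machinery on well-formed process descriptions, not robustness
to noisy real-world curation — the loader's row diagnostics and the
disjointness guard are the first line of defence there.

## Problem sizes and verification

The oracle-equivalence and fixpoint-law tests run on generated stores of
at most ~100 individuals (the naive re-evaluate-everything oracle is
quadratic and meant for small stores).  The scale test and the acceptance
script use ~1.5k metabolic reactions and ~1.7k assembly reactions
(≈18k individuals, ≈140k inferred assertions), chosen as the order of
magnitude of a bacterial cytosolic metabolic network; saturation takes
tens of seconds on one CPU.  Published-count reproduction for the two
curated instantiations (Calvin cycle, E. coli) depends on transcriptions
of the published supplementary spreadsheets, which this package does not
redistribute; the corresponding test states the expected headline counts
and fails until the transcriptions are supplied under `data/published/`.
Reproduction of those counts additionally depends on the exact published
rule catalogue (only four rules are published verbatim; the other 23 here
are reconstructions) and on the editor's counting convention, both
flagged above.

## Known limitations

* No owl:sameAs-style individual merging; distinct ids are distinct
  entities by assumption.
* `interacts_with` is materialised as written (directed); a config flag
  adds the symmetric closure.
* Defined-class "only" conditions are stored but not yet validated
  against the closed world (planned as a warning-level check).
* The property schema ships the 24 properties actually named by the
  model; sources disagree on the full property count and the remainder
  are not named anywhere recoverable.
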