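# prockb — process-centered biological knowledge bases with rule inference

Most molecular annotation is *gene-centered*: functions, cofactors and
pathway membership are pinned onto individual gene products, even when the
biologically active entity is a complex (its function ends up annotated on
every subunit, its cofactors on none of them).  `prockb` takes the
systems-biology viewpoint instead: the **biological process** is the anchor
of knowledge.  A metabolic reaction, a complex assembly or a
post-translational modification is described by a handful of declared
assertions — its inputs, outputs, mediator and activity — and a
forward-chaining rule engine derives everything else: molecule typing
(metabolite, kinase, complex subunit, coenzyme), complex composition,
function assignment, transient interactions and pathway participants.

It is aimed at systems biologists and bio-ontology curators who want
HermiT/SWRL-style ABox materialisation over a compact process ontology,
but as a scriptable Python library with explicit provenance and an
editable rule catalog.

## The model

The terminological layer (a YAML config, 141 classes) has three mutually
disjoint roots — `BiologicalProcess`, `Participant`, `Activity` — with a
65-class process hierarchy (maximum subclass depth 7).  Imported classes
keep their original GO/ChEBI/NCI Thesaurus IRIs.  An instantiation table
declares, per process *r*, assertions using seven core properties
(`has_input`, `has_output`, `mediated_by`, `requires`, `starts_with`,
`ends_with`, `has_intermediary_process`, plus `precedes` for ordering).

Saturation computes the least fixpoint of

* subsumption (`C(x), C ⊑ D ⊢ D(x)`), sub-property, inverse and
  domain/range entailments, and
* a catalog of 27 safe Horn rules `B₁ ∧ … ∧ Bₙ ⇒ H₁ ∧ … ∧ Hₘ` over class
  and property atoms with a `DifferentFrom` builtin (id inequality), e.g.
  the function-assignment rule

  ```
  MediatedProcess(?r) ∧ Participant(?p0) ∧ Activity(?a)
      ∧ mediated_by(?r, ?p0) ∧ requires(?r, ?a)  ⇒  has_function(?p0, ?a)
  ```

Rules are positive and create no new individuals, so the fixpoint exists,
is finite, and is independent of evaluation order.  Evaluation is
semi-naive (each new fact is joined once against the store through the
rule atoms it can instantiate).  Every inferred assertion carries the id
of the rule or entailment that produced it, and declared assertions are
never demoted.

## Worked example

`examples/simple_enzyme.py` describes one reaction — phosphorylation of
3-phosphoglycerate by phosphoglycerate kinase — with ten declared typing
rows and nine property rows, then saturates:

```
declared: 10 class / 9 property assertions on 10 individuals
inferred: 39 class / 31 property assertions (70 ledger entries)

Phosphoglycerate kinase 1 is now typed: ActiveEntity, Chemical, Enzyme,
GeneProduct, Kinase, Participant, Protein, SimpleProtein, Transferase
its function: Phosphoglycerate kinase activity
Mg-ATP decomposes into: ATP, Mg2+
```

The enzyme was declared only as a simple protein; its kinase typing, the
`has_function` link to its activity, the metabolite typing of the four
small molecules and the decomposition of Mg-ATP into Mg2+ and ATP are all
derived from the process description.  `examples/complex_enzyme.py` shows
the complex case: the RuBisCO holoenzyme ends up typed `ActiveEntity,
Holoenzyme, Lyase, Oxidoreductase, ProteinComplex` and carries the
carboxylase function, while the RBCL subunit only `contributes_to` it.

## Command line

```sh
prockb validate                        # schema + rule catalog checks
prockb generate --seed 1 --out net.csv # synthetic table + inference ledger
prockb reason --out run/ net.csv       # saturate: ontology, metrics, ledger
prockb diff run_a/saturated.trig run_b/saturated.trig
```

`reason` writes `metrics.{txt,json}` (declared/inferred counts, typing
coverage), the per-assertion `inference_ledger.tsv`, and a TriG export in
which declared and inferred assertions live in separate named graphs so
provenance survives a round trip.

## Layout

- `src/prockb/schema.py` — class/property schema, closure, disjointness
- `src/prockb/kb.py` — assertion store with declared/inferred provenance
- `src/prockb/rules.py` — rule catalog parsing and body matching
- `src/prockb/engine.py` — semi-naive saturation + pathway participants
- `src/prockb/table_io.py` — instantiation tables, RDF export, diffs
- `src/prockb/fixtures.py` — worked examples and the network generator
- `src/prockb/data/` — `core_schema.yaml`, `rules.yaml` (single sources
  of truth; swap in your own)
- `docs/methods.md` — model, assumptions, design choices, limitations
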