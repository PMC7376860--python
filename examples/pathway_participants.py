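"""Pathway participants with transient intermediates excluded.

A two-step chain A -> B -> C: B is produced by step 1 and immediately
consumed by step 2, so it is a transient intermediate and not a
participant of the pathway as a whole.
"""

from prockb import (KnowledgeBase, build_core_schema,
                    infer_pathway_participants)

kb = KnowledgeBase(build_core_schema())
kb.assert_class("glycolysis fragment", "MetabolicPathway")
for step in ("step 1", "step 2"):
    kb.assert_class(step, "MetabolicTransference")
kb.assert_property("glycolysis fragment", "starts_with", "step 1")
kb.assert_property("glycolysis fragment", "ends_with", "step 2")
kb.assert_property("step 1", "precedes", "step 2")
kb.assert_property("step 1", "has_input", "A")
kb.assert_property("step 1", "has_output", "B")
kb.assert_property("step 1", "mediated_by", "enzyme 1")
kb.assert_property("step 2", "has_input", "B")
kb.assert_property("step 2", "has_output", "C")
kb.assert_property("step 2", "mediated_by", "enzyme 2")

added = infer_pathway_participants(kb)
print("pathway participants:", sorted(a.object for a in added))
# A and C (the chain's endpoints) and both enzymes are participants;
# the intermediate B is excluded.
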