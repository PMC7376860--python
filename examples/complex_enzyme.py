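"""Complex assembly and activation: subunits vs the holoenzyme.

Builds the RuBisCO mini-network (chaperoned assembly, carbamylation,
magnesium binding, then carboxylation/oxygenation), saturates it, and
contrasts the annotation of the large subunit with the holoenzyme's.
"""

from prockb import (apply_rules_to_fixpoint, build_core_schema,
                    load_instantiation_table, load_rule_catalog)
from prockb.fixtures import rubisco_fixture

schema = build_core_schema()
rules = load_rule_catalog(None, schema)
kb = load_instantiation_table(rubisco_fixture(), schema)
apply_rules_to_fixpoint(kb, rules)

holo = "RuBisCO holoenzyme"
print(f"{holo} typed:", ", ".join(sorted(
    kb.classes_of(holo) - {"Participant", "Chemical", "GeneProduct"})))
print("RBCL typed:", ", ".join(sorted(
    kb.classes_of("RBCL") - {"Participant", "Chemical", "GeneProduct"})))
print("Mg2+ typed:", ", ".join(sorted(
    kb.classes_of("Mg2+") - {"Participant", "Chemical", "Non-geneProduct"})))

print("\nholoenzyme has_function:",
      [a.object for a in kb.query(subject=holo, property="has_function")])
print("RBCL has_function:",
      [a.object for a in kb.query(subject="RBCL", property="has_function")])
print("RBCL contributes_to:",
      [a.object for a in kb.query(subject="RBCL", property="contributes_to")])
# Function is anchored on the active complex; the subunit only contributes
# to it — the distinction gene-centred annotation cannot express.

print("\nactivation pathway participants:",
      ", ".join(sorted(kb.objects("RuBisCO activation pathway",
                                  "has_participant"))))
# The assembly/carbamylation intermediates are consumed by the next step
# and are therefore excluded from the pathway's participants.
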