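"""Independent oracles used by the test suite.

Everything here is deliberately naive and index-free: rule bodies are
matched by scanning full assertion lists, the fixpoint re-evaluates every
rule against the whole store each round, and pathway participants are
recomputed from scratch by set algebra.  None of the engine's semi-naive
machinery is reused, so agreement between the two is a meaningful check.
"""

from __future__ import annotations

from prockb.kb import INFERRED, KnowledgeBase


def naive_bindings(kb: KnowledgeBase, rule) -> list[dict]:
    """All body bindings, by plain scan-and-extend joins."""
    positives = [a for a in rule.body if a.kind != "different_from"]
    builtins = [a for a in rule.body if a.kind == "different_from"]
    bindings = [{}]
    class_list = [(a.individual, a.class_id) for a in kb.class_assertions()]
    prop_list = [(a.subject, a.property_id, a.object)
                 for a in kb.property_assertions()]
    for atom in positives:
        new = []
        for b in bindings:
            if atom.kind == "class":
                term = atom.args[0]
                for ind, cls in class_list:
                    if cls != atom.predicate:
                        continue
                    want = b.get(term.name) if term.is_var else term.name
                    if want is not None and want != ind:
                        continue
                    nb = dict(b)
                    if term.is_var:
                        nb[term.name] = ind
                    new.append(nb)
            else:
                st, ot = atom.args
                for s, p, o in prop_list:
                    if p != atom.predicate:
                        continue
                    ws = b.get(st.name) if st.is_var else st.name
                    wo = b.get(ot.name) if ot.is_var else ot.name
                    if ws is not None and ws != s:
                        continue
                    if wo is not None and wo != o:
                        continue
                    nb = dict(b)
                    if st.is_var:
                        nb[st.name] = s
                    if ot.is_var:
                        if ot.name in nb and nb[ot.name] != o:
                            continue
                        nb[ot.name] = o
                    new.append(nb)
        bindings = new
    out = []
    for b in bindings:
        ok = True
        for atom in builtins:
            l = b.get(atom.args[0].name) if atom.args[0].is_var else atom.args[0].name
            r = b.get(atom.args[1].name) if atom.args[1].is_var else atom.args[1].name
            if l == r:
                ok = False
                break
        if ok:
            out.append(b)
    # dedup
    seen, uniq = set(), []
    for b in out:
        key = tuple(sorted(b.items()))
        if key not in seen:
            seen.add(key)
            uniq.append(b)
    return uniq


def _schema_round(kb: KnowledgeBase) -> bool:
    changed = False
    for a in list(kb.class_assertions()):
        for parent in kb.schema.classes[a.class_id].parents:
            changed |= kb.assert_class(a.individual, parent, INFERRED, "subclass")
    for a in list(kb.property_assertions()):
        pdef = kb.schema.properties[a.property_id]
        if pdef.super_property:
            changed |= kb.assert_property(a.subject, pdef.super_property,
                                          a.object, INFERRED, "subproperty")
        if pdef.inverse:
            changed |= kb.assert_property(a.object, pdef.inverse, a.subject,
                                          INFERRED, "inverse")
        if pdef.domain:
            changed |= kb.assert_class(a.subject, pdef.domain, INFERRED, "domain")
        if pdef.range:
            changed |= kb.assert_class(a.object, pdef.range, INFERRED, "range")
    return changed


def _pathway_round(kb: KnowledgeBase) -> bool:
    schema = kb.schema
    pathway_classes = schema.subclasses("Pathway")
    changed = False
    class_list = [(a.individual, a.class_id) for a in kb.class_assertions()]
    prop_list = [(a.subject, a.property_id, a.object)
                 for a in kb.property_assertions()]
    pathways = {i for i, c in class_list if c in pathway_classes}
    for pw in sorted(pathways):
        procs = {o for s, p, o in prop_list if s == pw and p in
                 ("starts_with", "ends_with", "has_intermediary_process",
                  "has_subprocess")}
        if not procs:
            continue
        edges = [(s, o) for s, p, o in prop_list
                 if p == "precedes" and s in procs and o in procs]
        participants = {o for s, p, o in prop_list if s in procs and p in
                        ("has_input", "has_output", "mediated_by")}
        transient = set()
        for a, b in edges:
            outs = {o for s, p, o in prop_list if s == a and p == "has_output"}
            ins = {o for s, p, o in prop_list if s == b and p == "has_input"}
            transient |= outs & ins
        for x in participants - transient:
            changed |= kb.assert_property(pw, "has_participant", x,
                                          INFERRED, "pathway")
    return changed


def naive_saturate(kb: KnowledgeBase, rules, pathway: bool = True
                   ) -> KnowledgeBase:
    """Re-evaluate everything each round until nothing changes."""
    changed = True
    while changed:
        changed = _schema_round(kb)
        for rule in rules:
            for b in naive_bindings(kb, rule):
                for atom in rule.head:
                    if atom.kind == "class":
                        ind = b.get(atom.args[0].name) if atom.args[0].is_var \
                            else atom.args[0].name
                        changed |= kb.assert_class(ind, atom.predicate,
                                                   INFERRED, rule.id)
                    else:
                        s = b.get(atom.args[0].name) if atom.args[0].is_var \
                            else atom.args[0].name
                        o = b.get(atom.args[1].name) if atom.args[1].is_var \
                            else atom.args[1].name
                        changed |= kb.assert_property(s, atom.predicate, o,
                                                      INFERRED, rule.id)
        if pathway:
            changed |= _pathway_round(kb)
    return kb
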