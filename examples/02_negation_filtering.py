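"""Negation detection on canonical clinical phrasings.

Trigger phrases open a bounded scope inside the sentence; extracted terms
whose spans fall inside a scope are flagged and, with the kappa switch on,
removed before integration.
"""

from clinex import (
    ExtractedTerm,
    apply_negation_filter,
    detect_negation_spans,
    flag_negated,
    load_negation_lexicon,
)

lexicon = load_negation_lexicon()
text = "no fracture. patient denies a headache. Orthostatic hypotension proven."

spans = detect_negation_spans(text, lexicon)
for s in spans:
    print(f"negated scope {text[s.start:s.end]!r} (trigger {s.trigger!r})")

terms = [
    ExtractedTerm("fracture", (3, 11), "medical_condition", "demo"),
    ExtractedTerm("headache", (30, 38), "medical_condition", "demo"),
    ExtractedTerm("Orthostatic hypotension", (40, 63), "medical_condition", "demo"),
]
flagged = flag_negated(terms, spans, text)
for t in flagged:
    print(f"{t.surface!r}: negated={t.negated}")

kept = apply_negation_filter(flagged, kappa=True)
print(f"\nkappa=True keeps {[t.surface for t in kept]}")
# only the asserted finding survives; the two negated mentions are dropped.
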