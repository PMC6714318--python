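"""Term-similarity weights and entity merging.

Two extractors report the same clinical concept under different surface
forms; their ranked code lists overlap, the pair weight exceeds gamma, and
the mentions merge into one entity.
"""

from clinex import ConceptMatch, ExtractedTerm, NormalizedTerm, merge_terms, pair_similarity


def norm(surface, extractor_id, codes, span):
    return NormalizedTerm(
        term=ExtractedTerm(surface=surface, span=span,
                           category="medical_condition", extractor_id=extractor_id),
        matches=tuple(
            ConceptMatch(code_system="CUI", code=c, rank=i + 1) for i, c in enumerate(codes)
        ),
    )


a = norm("orthostatic hypotension", "watson",
         ["C0020651", "C0020649", "C0684384", "C1720824"], span=(0, 23))
b = norm("postural hypotension", "textrazor",
         ["C0020651", "C0020649", "C0948841"], span=(0, 20))

sim = pair_similarity(a, b)
print(f"alpha = {sim.alpha:.2f} (shared codes over the 10 candidate slots)")
print(f"beta  = {sim.beta:.2f} (shared codes within the top 3)")
print(f"weight = alpha/4 + 3*beta/4 = {sim.weight:.3f}")

entities = merge_terms([a, b], gamma=0.1)
print(f"\nat gamma = 0.1 the two mentions merge into {len(entities)} entity:")
entity = entities[0]
print(f"  representative: {entity.surface!r}, extractors: {sorted(entity.extractor_ids)}")
# weight 0.55 > 0.1: the two surface forms denote the same concept, so the
# cluster is credited to both extractors when weights are summed.
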