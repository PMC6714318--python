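"""The worked integration example: agreement decides acceptance.

Six extractors with uniform weights (1/6 each) and threshold theta = 0.35:
a concept reported by only two extractors accumulates weight 1/3 and is
rejected as a likely false extraction, while one reported by five of six
accumulates 5/6 and is accepted.
"""

from clinex import (
    ConceptMatch,
    ExtractedTerm,
    IntegrationConfig,
    NormalizedTerm,
    integrate,
    uniform_omega,
)


def supported_by(surface, codes, n):
    return {
        f"api{i}": [
            NormalizedTerm(
                term=ExtractedTerm(surface=surface, span=(0, len(surface)),
                                   category="medical_condition", extractor_id=f"api{i}"),
                matches=tuple(
                    ConceptMatch(code_system="CUI", code=c, rank=k + 1)
                    for k, c in enumerate(codes)
                ),
            )
        ]
        for i in range(n)
    }


config = IntegrationConfig(
    kappa=False, gamma=0.1, theta=0.35,
    omega=uniform_omega([f"api{i}" for i in range(6)]),
)

for surface, codes, n in [
    ("hematoma", ["C0018944", "C0852397"], 2),
    ("orthostatic hypotension", ["C0020651", "C0020649"], 5),
]:
    result = integrate(supported_by(surface, codes, n), config)
    for entity, verdict in (
        [(e, "ACCEPTED") for e in result.accepted_entities]
        + [(e, "rejected") for e in result.rejected_entities]
    ):
        print(
            f"{entity.surface!r}: found by {n}/6 extractors, "
            f"cumulative weight {entity.cumulative_weight:.3f} -> {verdict}"
        )
# weight 0.333 <= theta=0.35 rejects; 0.833 > 0.35 accepts.
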