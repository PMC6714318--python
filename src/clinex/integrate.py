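"""Double-weight integration of multiple extractors' outputs.

Two weight systems turn heterogeneous per-extractor term lists into one
set of document entities:

1. **Term similarity.** Two normalized terms are compared through their
   ranked code lists: with alpha the fraction of shared codes over all 10
   candidate slots and beta the fraction shared within the top 3,

       weight = alpha / 4 + 3 * beta / 4

   and the pair counts as the same concept when weight is strictly greater
   than the similarity threshold gamma. Entities are the connected
   components of this "equal term" relation (transitive closure), so the
   partition does not depend on input order.

2. **Extractor confidence.** Each extractor carries a weight omega
   (typically its held-out F1, sum-normalized over the roster). An entity's
   cumulative weight is the sum of omega over the *distinct* extractors
   that produced any of its member mentions; the entity is accepted when
   that sum is strictly greater than the extractor threshold theta,
   otherwise it is rejected as a likely false extraction.

Recommended starting point: gamma = 0.1, theta = 0.35, negation filter off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus import ExtractionResult
from .errors import ConfigurationError, ValidationError
from .normalize import MAX_MATCHES, TOP_RANKS, NormalizedTerm


@dataclass(frozen=True)
class PairSimilarity:
    """Similarity of two terms' ranked code lists; weight = alpha/4 + 3*beta/4."""

    alpha: float
    beta: float

    @property
    def weight(self) -> float:
        return self.alpha / 4.0 + 3.0 * self.beta / 4.0


@dataclass
class MergedEntity:
    """A cluster of equivalent terms with its contributing extractors."""

    members: list[NormalizedTerm]
    representative: NormalizedTerm
    extractor_ids: frozenset[str]
    cumulative_weight: float = 0.0

    @property
    def surface(self) -> str:
        return self.representative.term.surface

    @property
    def primary_code(self) -> tuple[str, str] | None:
        return self.representative.primary_code

    def code_keys(self) -> set[tuple[str, str]]:
        """Primary codes of all members (a merged synonym cluster can match
        gold through any of them)."""
        return {m.primary_code for m in self.members if m.primary_code is not None}

    def surface_keys(self) -> set[str]:
        return {m.normalized_surface for m in self.members}

    def to_dict(self) -> dict:
        return {
            "surface": self.surface,
            "primary_code": list(self.primary_code) if self.primary_code else None,
            "extractor_ids": sorted(self.extractor_ids),
            "cumulative_weight": self.cumulative_weight,
            "members": [m.to_dict() for m in self.members],
            "representative": self.representative.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MergedEntity":
        return cls(
            members=[NormalizedTerm.from_dict(m) for m in d["members"]],
            representative=NormalizedTerm.from_dict(d["representative"]),
            extractor_ids=frozenset(d["extractor_ids"]),
            cumulative_weight=float(d["cumulative_weight"]),
        )


@dataclass(frozen=True)
class IntegrationConfig:
    """Pipeline hyperparameters.

    kappa: negation filter on/off; gamma: term-similarity threshold in
    [0, 1]; theta: cumulative extractor-weight threshold in [0, 1]; omega:
    per-extractor weights (normalized to sum 1 when estimated from F1s).
    """

    kappa: bool = False
    gamma: float = 0.1
    theta: float = 0.35
    omega: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValidationError(f"gamma {self.gamma} outside [0, 1]")
        if not 0.0 <= self.theta <= 1.0:
            raise ValidationError(f"theta {self.theta} outside [0, 1]")
        for ex, w in self.omega.items():
            if not 0.0 <= w <= 1.0:
                raise ValidationError(f"omega[{ex!r}] = {w} outside [0, 1]")

    def to_dict(self) -> dict:
        return {"kappa": self.kappa, "gamma": self.gamma,
                "theta": self.theta, "omega": dict(self.omega)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "IntegrationConfig":
        return cls(kappa=bool(d.get("kappa", False)),
                   gamma=float(d.get("gamma", 0.1)),
                   theta=float(d.get("theta", 0.35)),
                   omega=dict(d.get("omega", {})))


def pair_similarity(a: NormalizedTerm, b: NormalizedTerm) -> PairSimilarity:
    """Overlap of two terms' ranked code lists.

    alpha = |codes(a) ∩ codes(b)| / 10 over the full candidate lists and
    beta = |top3(a) ∩ top3(b)| / 3; the denominators are the fixed list
    capacities, not the actual lengths, so shorter lists can only lower the
    score. Either list empty forces alpha = beta = 0. Symmetric.
    """
    if not a.matches or not b.matches:
        return PairSimilarity(0.0, 0.0)
    codes_a = {m.key for m in a.matches}
    codes_b = {m.key for m in b.matches}
    top_a = {m.key for m in a.matches[:TOP_RANKS]}
    top_b = {m.key for m in b.matches[:TOP_RANKS]}
    alpha = len(codes_a & codes_b) / MAX_MATCHES
    beta = len(top_a & top_b) / TOP_RANKS
    return PairSimilarity(alpha, beta)


def are_equal_terms(sim: PairSimilarity, gamma: float) -> bool:
    """Strictly greater than gamma — a weight exactly at threshold is not
    merged."""
    return sim.weight > gamma


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _entity_sort_key(t: NormalizedTerm, idx: int) -> tuple:
    start = t.term.span[0] if t.term.span else 1 << 30
    return (-len(t.matches), start, t.term.surface, idx)


def merge_terms(terms: Sequence[NormalizedTerm], gamma: float) -> list[MergedEntity]:
    """Cluster one document's terms into entities.

    Entities are connected components of the graph whose edges are pairs
    with similarity weight > gamma. The representative is the member with
    the most code matches (ties: earliest span, then lexicographic
    surface). Output order is deterministic and the partition is invariant
    to input order.
    """
    terms = list(terms)
    uf = _UnionFind(len(terms))
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            if are_equal_terms(pair_similarity(terms[i], terms[j]), gamma):
                uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(len(terms)):
        components.setdefault(uf.find(i), []).append(i)

    entities = []
    for indices in components.values():
        rep_idx = min(indices, key=lambda i: _entity_sort_key(terms[i], i))
        members = [terms[i] for i in sorted(indices)]
        entities.append(
            MergedEntity(
                members=members,
                representative=terms[rep_idx],
                extractor_ids=frozenset(m.term.extractor_id for m in members),
            )
        )
    entities.sort(
        key=lambda e: (
            e.representative.term.span[0] if e.representative.term.span else 1 << 30,
            e.surface,
        )
    )
    return entities


def cumulative_weight(entity: MergedEntity, omega: Mapping[str, float]) -> float:
    """Sum omega over the entity's distinct extractors (an extractor counts
    once no matter how many member mentions it produced)."""
    missing = entity.extractor_ids - omega.keys()
    if missing:
        raise ConfigurationError(
            f"no omega weight for extractor(s): {', '.join(sorted(missing))}"
        )
    return sum(omega[ex] for ex in entity.extractor_ids)


def uniform_omega(extractor_ids: Sequence[str]) -> dict[str, float]:
    """Equal weights summing to 1 over a roster."""
    if not extractor_ids:
        raise ConfigurationError("cannot build weights for an empty roster")
    w = 1.0 / len(extractor_ids)
    return {ex: w for ex in extractor_ids}


def integrate(
    per_extractor_terms: Mapping[str, Sequence[NormalizedTerm]],
    config: IntegrationConfig,
    doc_id: str = "",
) -> ExtractionResult:
    """Pool all extractors' (already negation-filtered, per-extractor
    deduplicated) terms for one document, merge equivalent terms at gamma,
    and accept each entity iff its cumulative extractor weight strictly
    exceeds theta. Accepted and rejected lists are each sorted by
    descending weight, then surface.
    """
    pooled: list[NormalizedTerm] = []
    for extractor_id in sorted(per_extractor_terms):
        pooled.extend(per_extractor_terms[extractor_id])

    entities = merge_terms(pooled, config.gamma)
    for entity in entities:
        entity.cumulative_weight = cumulative_weight(entity, config.omega)

    accepted = [e for e in entities if e.cumulative_weight > config.theta]
    rejected = [e for e in entities if e.cumulative_weight <= config.theta]
    key = lambda e: (-e.cumulative_weight, e.surface)  # noqa: E731
    return ExtractionResult(
        doc_id=doc_id,
        accepted_entities=sorted(accepted, key=key),
        rejected_entities=sorted(rejected, key=key),
        config_used=config,
    )
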