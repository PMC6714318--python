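"""Double-weight integration: pair similarity, merging, cumulative weights."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinex import (
    ConfigurationError,
    IntegrationConfig,
    are_equal_terms,
    cumulative_weight,
    integrate,
    merge_terms,
    pair_similarity,
    uniform_omega,
)

from conftest import make_norm


def brute_force_similarity(codes_a, codes_b):
    """Independent oracle: explicit loops over the two ranked lists."""
    shared_all = 0
    for c in set(codes_a):
        if c in codes_b:
            shared_all += 1
    shared_top = 0
    for c in set(codes_a[:3]):
        if c in codes_b[:3]:
            shared_top += 1
    if not codes_a or not codes_b:
        return 0.0, 0.0
    return shared_all / 10.0, shared_top / 3.0


def random_code_list(rng, max_len=10):
    n = rng.randint(0, max_len)
    pool = [f"C{k}" for k in range(15)]
    return rng.sample(pool, n)


class TestPairSimilarity:
    def test_identical_full_lists_weight_one(self):
        codes = [f"C{i}" for i in range(10)]
        sim = pair_similarity(make_norm(codes), make_norm(codes))
        assert sim.alpha == 1.0 and sim.beta == 1.0 and sim.weight == 1.0

    def test_disjoint_lists_weight_zero(self):
        sim = pair_similarity(make_norm(["C1", "C2"]), make_norm(["C3", "C4"]))
        assert sim.weight == 0.0

    def test_two_shared_overall_one_shared_top3(self):
        a = make_norm(["C1", "C2", "C3", "C4"])
        b = make_norm(["C1", "C9", "C8", "C4"])
        sim = pair_similarity(a, b)
        assert sim.alpha == pytest.approx(0.2)
        assert sim.beta == pytest.approx(1 / 3)
        assert sim.weight == pytest.approx(0.30)

    def test_empty_match_list_forces_zero(self):
        sim = pair_similarity(make_norm([]), make_norm(["C1"]))
        assert sim.alpha == sim.beta == 0.0

    def test_matches_brute_force_oracle(self):
        rng = random.Random(20240101)
        for _ in range(300):
            codes_a = random_code_list(rng)
            codes_b = random_code_list(rng)
            sim = pair_similarity(make_norm(codes_a), make_norm(codes_b))
            alpha, beta = brute_force_similarity(codes_a, codes_b)
            assert sim.alpha == pytest.approx(alpha)
            assert sim.beta == pytest.approx(beta)
            assert 0.0 <= sim.weight <= 1.0

    def test_symmetry(self):
        rng = random.Random(7)
        for _ in range(100):
            a = make_norm(random_code_list(rng))
            b = make_norm(random_code_list(rng))
            assert pair_similarity(a, b) == pair_similarity(b, a)

    def test_weight_monotone_in_overlap(self):
        # growing the shared prefix never lowers the weight
        base = [f"C{i}" for i in range(10)]
        other = [f"D{i}" for i in range(10)]
        prev = -1.0
        for k in range(11):
            b = base[:k] + other[: 10 - k]
            w = pair_similarity(make_norm(base), make_norm(b)).weight
            assert w >= prev
            prev = w


class TestEqualTerms:
    def test_above_gamma_is_equal(self):
        a = make_norm(["C1", "C2", "C3", "C4"])
        b = make_norm(["C1", "C9", "C8", "C4"])
        assert are_equal_terms(pair_similarity(a, b), gamma=0.1)

    def test_zero_weight_never_equal(self):
        sim = pair_similarity(make_norm([]), make_norm([]))
        assert not are_equal_terms(sim, gamma=0.0)

    def test_weight_exactly_at_threshold_not_equal(self):
        a = make_norm(["C1", "C2", "C3", "C4"])
        b = make_norm(["C1", "C9", "C8", "C4"])
        sim = pair_similarity(a, b)
        assert not are_equal_terms(sim, gamma=sim.weight)


def random_terms(rng, n, extractors=("a", "b", "c")):
    return [
        make_norm(
            random_code_list(rng, max_len=6),
            surface=f"t{i}",
            extractor_id=rng.choice(extractors),
            span=(i * 10, i * 10 + 5),
        )
        for i in range(n)
    ]


def oracle_partition(terms, gamma):
    """Connected components via networkx — independent of the union-find."""
    g = nx.Graph()
    g.add_nodes_from(range(len(terms)))
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            alpha, beta = brute_force_similarity(
                [m.key for m in terms[i].matches], [m.key for m in terms[j].matches]
            )
            if alpha / 4 + 3 * beta / 4 > gamma:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestMergeTerms:
    def test_singleton(self):
        [entity] = merge_terms([make_norm(["C1"])], gamma=0.1)
        assert len(entity.members) == 1

    def test_transitive_chain_merges(self):
        a = make_norm(["C1", "C2", "C3"], surface="a", span=(0, 1))
        b = make_norm(["C3", "C4", "C5"], surface="b", span=(2, 3))
        c = make_norm(["C5", "C6", "C7"], surface="c", span=(4, 5))
        assert not are_equal_terms(pair_similarity(a, c), 0.1)
        [entity] = merge_terms([a, b, c], gamma=0.1)
        assert len(entity.members) == 3

    def test_gamma_one_keeps_everything_separate(self):
        terms = random_terms(random.Random(3), 6)
        assert len(merge_terms(terms, gamma=1.0)) == len(terms)

    def test_matches_networkx_oracle(self):
        rng = random.Random(99)
        for _ in range(100):
            terms = random_terms(rng, rng.randint(0, 12))
            gamma = rng.choice([0.0, 0.1, 0.25, 0.5])
            entities = merge_terms(terms, gamma)
            got = {
                frozenset(terms.index(m) for m in e.members) for e in entities
            }
            assert got == oracle_partition(terms, gamma)

    def test_partition_invariant_to_input_order(self):
        rng = random.Random(5)
        terms = random_terms(rng, 8)
        shuffled = terms[:]
        rng.shuffle(shuffled)
        keys = lambda ents: {frozenset(m.term.surface for m in e.members) for e in ents}  # noqa: E731
        assert keys(merge_terms(terms, 0.1)) == keys(merge_terms(shuffled, 0.1))

    def test_entity_count_non_decreasing_in_gamma(self):
        terms = random_terms(random.Random(11), 10)
        counts = [len(merge_terms(terms, g)) for g in (0.0, 0.1, 0.3, 0.6, 1.0)]
        assert counts == sorted(counts)

    def test_representative_has_most_matches(self):
        rich = make_norm(["C1", "C2", "C3", "C4"], surface="rich", span=(5, 9))
        poor = make_norm(["C1", "C2", "C3"], surface="poor", span=(0, 4))
        [entity] = merge_terms([poor, rich], gamma=0.1)
        assert entity.representative is rich


class TestCumulativeWeight:
    def test_sum_over_distinct_extractors(self):
        a = make_norm(["C1"], extractor_id="A")
        b = make_norm(["C1"], extractor_id="B", span=(2, 8))
        [entity] = merge_terms([a, b], gamma=0.1)
        omega = {"A": 0.4, "B": 0.3, "C": 0.3}
        assert cumulative_weight(entity, omega) == pytest.approx(0.7)

    def test_extractor_counts_once_despite_many_mentions(self):
        a1 = make_norm(["C1"], extractor_id="A", span=(0, 6))
        a2 = make_norm(["C1"], extractor_id="A", span=(10, 16))
        [entity] = merge_terms([a1, a2], gamma=0.1)
        assert cumulative_weight(entity, {"A": 0.4}) == pytest.approx(0.4)

    def test_uniform_sixth(self):
        omega = uniform_omega([f"x{i}" for i in range(6)])
        a = make_norm(["C1"], extractor_id="x0")
        [entity] = merge_terms([a], gamma=0.1)
        assert cumulative_weight(entity, omega) == pytest.approx(1 / 6)

    def test_unknown_extractor_is_configuration_error(self):
        [entity] = merge_terms([make_norm(["C1"], extractor_id="ghost")], gamma=0.1)
        with pytest.raises(ConfigurationError, match="ghost"):
            cumulative_weight(entity, {"A": 1.0})


class TestIntegrate:
    def six_extractor_input(self, n_supporting, codes=("C1", "C2", "C3")):
        return {
            f"x{i}": [make_norm(list(codes), extractor_id=f"x{i}")]
            for i in range(n_supporting)
        }

    def test_two_of_six_rejected_five_of_six_accepted(self):
        omega = uniform_omega([f"x{i}" for i in range(6)])
        config = IntegrationConfig(gamma=0.1, theta=0.35, omega=omega)
        result2 = integrate(self.six_extractor_input(2), config)
        assert not result2.accepted_entities
        assert result2.rejected_entities[0].cumulative_weight == pytest.approx(1 / 3)
        result5 = integrate(self.six_extractor_input(5), config)
        assert not result5.rejected_entities
        assert result5.accepted_entities[0].cumulative_weight == pytest.approx(5 / 6)

    def test_empty_input(self):
        result = integrate({}, IntegrationConfig(omega={}))
        assert result.accepted_entities == [] and result.rejected_entities == []

    def test_single_extractor_full_weight_accepted(self):
        config = IntegrationConfig(theta=0.35, omega={"solo": 1.0})
        result = integrate({"solo": [make_norm(["C1"], extractor_id="solo")]}, config)
        assert result.accepted_entities[0].cumulative_weight == 1.0

    def test_accepted_and_rejected_disjoint_and_sorted(self):
        omega = uniform_omega(["a", "b", "c"])
        terms = {
            "a": [make_norm(["C1"], surface="s1", extractor_id="a"),
                  make_norm(["D1"], surface="s2", extractor_id="a", span=(10, 12))],
            "b": [make_norm(["C1"], surface="s1", extractor_id="b")],
            "c": [make_norm(["C1"], surface="s1", extractor_id="c")],
        }
        result = integrate(terms, IntegrationConfig(theta=0.35, omega=omega))
        accepted = {id(e) for e in result.accepted_entities}
        rejected = {id(e) for e in result.rejected_entities}
        assert not accepted & rejected
        weights = [e.cumulative_weight for e in result.accepted_entities]
        assert weights == sorted(weights, reverse=True)

    def test_theta_monotonicity(self):
        rng = random.Random(21)
        omega = uniform_omega(["a", "b", "c"])
        per_extractor = {
            ex: random_terms(rng, 5, extractors=(ex,)) for ex in ("a", "b", "c")
        }
        previous = None
        for theta in (0.2, 0.4, 0.7, 0.9):
            config = IntegrationConfig(theta=theta, omega=omega)
            accepted = {
                frozenset(m.term.surface for m in e.members)
                for e in integrate(per_extractor, config).accepted_entities
            }
            if previous is not None:
                assert accepted <= previous
            previous = accepted

    def test_invariant_to_extractor_order(self):
        rng = random.Random(31)
        omega = uniform_omega(["a", "b", "c"])
        per_extractor = {
            ex: random_terms(rng, 4, extractors=(ex,)) for ex in ("a", "b", "c")
        }
        config = IntegrationConfig(omega=omega)
        forward = integrate(dict(per_extractor), config)
        backward = integrate(dict(reversed(list(per_extractor.items()))), config)
        key = lambda r: [  # noqa: E731
            (e.surface, round(e.cumulative_weight, 12)) for e in r.accepted_entities
        ]
        assert key(forward) == key(backward)


@settings(deadline=None, max_examples=80)
@given(st.data())
def test_pair_weight_bounds_property(data):
    pool = [f"C{k}" for k in range(12)]
    codes_a = data.draw(st.lists(st.sampled_from(pool), unique=True, max_size=10))
    codes_b = data.draw(st.lists(st.sampled_from(pool), unique=True, max_size=10))
    sim = pair_similarity(make_norm(codes_a), make_norm(codes_b))
    assert 0.0 <= sim.weight <= 1.0
    if sim.weight == 0.0:
        assert sim.alpha == 0.0 and sim.beta == 0.0
    if sim.weight == 1.0:
        assert sim.alpha == 1.0 and sim.beta == 1.0
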