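"""The polynomial-collapsing core: indicators, aggregation, collapse, folding."""

import random
from fractions import Fraction
from itertools import chain, combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigreach.network import build_network, maximal_deterministic, prune_for_pair
from sigreach.oracle import brute_force_reachability
from sigreach.reach import (
    Stage,
    StagePolynomial,
    advance_stage,
    aggregate_edge,
    c_indicator,
    chi,
    collapse,
    omega,
    reachability_probability,
)
from sigreach.separators import greedy_separator_sequence, trivial_separator_sequence
from sigreach.synthgen import fixture

from conftest import random_network


def _subsets(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def _fig2_det():
    return maximal_deterministic(fixture("fig2"))


class TestChi:
    def test_fig2_path_example(self):
        assert chi(_fig2_det(), {"1"}, "8", {1, 2, 5, 6, 7, 10, 11}) == 1

    def test_member_of_source_set_reachable_by_empty_path(self):
        assert chi(_fig2_det(), {"4"}, "4", set()) == 1

    def test_nonmember_unreachable_without_edges(self):
        assert chi(_fig2_det(), {"1"}, "8", set()) == 0

    def test_multi_source_form(self):
        det = _fig2_det()
        for u in det.nodes:
            for I in ({1, 3}, {2, 5, 6}, set(), {6, 7, 10}):
                combined = chi(det, {"1", "3"}, u, I)
                product_form = 1 - (1 - chi(det, {"1"}, u, I)) * (
                    1 - chi(det, {"3"}, u, I)
                )
                assert combined == product_form


def _minimal_cuts(net, s, v):
    """All minimal s-v edge cuts of the maximal deterministic network."""
    det = maximal_deterministic(net)
    all_idx = frozenset(e.index for e in det.edges)
    cuts = [
        frozenset(k)
        for k in _subsets(all_idx)
        if chi(det, {s}, v, all_idx - frozenset(k)) == 0
    ]
    return [k for k in cuts if not any(c < k for c in cuts)]


class TestOmega:
    def test_fig2_cut_example(self):
        # {e3, e5} is a minimal 1-8 cut with indices inside the absent set
        assert omega(_fig2_det(), {"1"}, "8", {2, 3, 4, 5}) == 1

    def test_no_cut_available(self):
        assert omega(_fig2_det(), {"1"}, "8", set()) == 0

    def test_operational_form_matches_minimal_cut_enumeration(self):
        rng = random.Random(11)
        for _ in range(12):
            net = random_network(rng, n_nodes_range=(4, 5), n_edges_range=(3, 8))
            det = maximal_deterministic(net)
            nodes = sorted(net.nodes)
            s, v = rng.sample(nodes, 2)
            cuts = _minimal_cuts(net, s, v)
            all_idx = [e.index for e in det.edges]
            for absent in map(frozenset, _subsets(all_idx)):
                literal = int(any(k <= absent for k in cuts))
                assert omega(det, {s}, v, absent) == literal


def _single_edge_stage(p=0.8):
    net = build_network([("s", "u", p)])
    return Stage.from_network(net, {"s"}, {"u"}, {1})


class TestCIndicator:
    def test_fully_decided_stage_has_exactly_one_T(self):
        stage = _single_edge_stage()
        for I in (frozenset(), frozenset({1})):
            hits = [
                T
                for T in map(frozenset, _subsets({"u"}))
                if c_indicator(stage, {"s"}, T, I, {1}) == 1
            ]
            assert len(hits) == 1

    def test_nothing_decided_yields_no_T(self):
        stage = _single_edge_stage()
        for T in map(frozenset, _subsets({"u"})):
            assert c_indicator(stage, {"s"}, T, frozenset(), frozenset()) == 0

    def test_at_most_one_T_on_random_stages(self):
        rng = random.Random(13)
        for _ in range(10):
            net = random_network(rng, n_nodes_range=(4, 5), n_edges_range=(3, 6))
            nodes = sorted(net.nodes)
            s = nodes[0]
            K_next = frozenset(rng.sample(nodes[1:], 2))
            stage = Stage.from_network(
                net, {s}, K_next, {e.index for e in net.edges}
            )
            idx = [e.index for e in net.edges]
            for theta in map(frozenset, _subsets(idx)):
                for I in map(frozenset, _subsets(theta)):
                    hits = sum(
                        c_indicator(stage, {s}, T, I, theta)
                        for T in map(frozenset, _subsets(K_next))
                    )
                    assert hits in (0, 1)


class TestAggregateAndCollapse:
    def test_aggregate_splits_single_term(self):
        stage = _single_edge_stage(p=0.5)
        poly = StagePolynomial(stage=stage)
        poly.open_terms[(frozenset({"s"}), frozenset())] = 1.0
        aggregate_edge(poly, 1)
        assert poly.open_terms == {
            (frozenset({"s"}), frozenset({1})): 0.5,
            (frozenset({"s"}), frozenset()): 0.5,
        }
        assert poly.coefficient_sum() == pytest.approx(1.0)

    def test_collapsed_term_absorbs_edge(self):
        stage = _single_edge_stage(p=0.8)
        poly = StagePolynomial(stage=stage)
        poly.collapsed[frozenset({"u"})] = 0.3
        aggregate_edge(poly, 1)
        assert poly.collapsed == {frozenset({"u"}): 0.3}
        assert not poly.open_terms

    def test_certain_edge_prunes_absent_branch(self):
        stage = _single_edge_stage(p=1.0)
        poly = StagePolynomial(stage=stage)
        poly.open_terms[(frozenset({"s"}), frozenset())] = 1.0
        aggregate_edge(poly, 1)
        assert list(poly.open_terms) == [(frozenset({"s"}), frozenset({1}))]

    def test_double_aggregation_rejected(self):
        stage = _single_edge_stage()
        poly = StagePolynomial(stage=stage)
        poly.open_terms[(frozenset({"s"}), frozenset())] = 1.0
        aggregate_edge(poly, 1)
        with pytest.raises(ValueError, match="already aggregated"):
            aggregate_edge(poly, 1)

    def test_single_edge_stage_collapses_fully(self):
        stage = _single_edge_stage(p=0.8)
        poly = StagePolynomial(stage=stage)
        poly.open_terms[(frozenset({"s"}), frozenset())] = 1.0
        aggregate_edge(poly, 1)
        collapse(poly)
        assert not poly.open_terms
        assert poly.collapsed[frozenset({"u"})] == pytest.approx(0.8)
        assert poly.collapsed[frozenset()] == pytest.approx(0.2)

    def test_early_collapse_before_stage_end(self):
        # two parallel routes s->u; once the first edge is present the
        # outcome is determined even though the second is undecided
        net = build_network([("s", "u", 0.5), ("s", "u2", 0.5), ("u2", "u", 0.5)])
        stage = Stage.from_network(net, {"s"}, {"u"}, {1, 2, 3})
        poly = StagePolynomial(stage=stage)
        poly.open_terms[(frozenset({"s"}), frozenset())] = 1.0
        aggregate_edge(poly, 1)
        collapse(poly)
        assert poly.collapsed == {frozenset({"u"}): 0.5}
        assert len(poly.open_terms) == 1  # absent branch still open


def _def3_subset_reachability(net, s, stage_edges, K):
    """Brute-force p({s}, T, K) by enumerating stage-edge configurations."""
    edges = [e for e in net.edges if e.index in stage_edges]
    det = maximal_deterministic(net)
    out = {}
    for present in map(frozenset, _subsets([e.index for e in edges])):
        prob = 1.0
        for e in edges:
            prob *= e.p if e.index in present else 1 - e.p
        T = frozenset(u for u in K if chi(det, {s}, u, present))
        out[T] = out.get(T, 0.0) + prob
    return out


class TestAdvanceStage:
    def test_base_case_source_polynomial(self):
        # the probability to reach the source itself is 1
        net = prune_for_pair(fixture("fig3"), "1", "7")
        seq = greedy_separator_sequence(net, "1", "7")
        assert seq.separators[0] == frozenset({"1"})
        prev = {frozenset({"1"}): 1.0}
        stage = Stage.from_network(net, seq.separators[0], seq.separators[1], seq.stages[0])
        out = advance_stage(prev, stage, method="terms")
        assert sum(out.values()) == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["terms", "frontier"])
    def test_first_stage_matches_subset_reachability_oracle(self, method):
        net = prune_for_pair(fixture("fig3"), "1", "7")
        seq = greedy_separator_sequence(net, "1", "7")
        K1 = seq.separators[1]
        stage = Stage.from_network(net, seq.separators[0], K1, seq.stages[0])
        got = advance_stage({frozenset({"1"}): 1.0}, stage, method=method)
        expected = _def3_subset_reachability(net, "1", seq.stages[0], K1)
        for T in set(got) | set(expected):
            assert got.get(T, 0.0) == pytest.approx(expected.get(T, 0.0), abs=1e-12)

    def test_uncollapsed_input_rejected(self):
        stage = _single_edge_stage()
        with pytest.raises(ValueError, match="not a subset"):
            advance_stage({frozenset({"zzz"}): 1.0}, stage)


class TestReachabilityProbability:
    def test_series_product(self):
        assert reachability_probability(fixture("series3"), "s", "t") == pytest.approx(0.25)

    def test_two_disjoint_paths(self):
        assert reachability_probability(fixture("parallel2"), "s", "t") == pytest.approx(0.4375)

    def test_bridge(self):
        assert reachability_probability(fixture("bridge5"), "s", "t") == pytest.approx(15 / 32)

    def test_bridge_exact_rational(self):
        assert reachability_probability(
            fixture("bridge5"), "s", "t", exact=True
        ) == Fraction(15, 32)

    def test_same_node_rejected(self):
        with pytest.raises(Exception, match="differ"):
            reachability_probability(fixture("series3"), "s", "s")

    def test_unknown_node_rejected(self):
        with pytest.raises(Exception, match="zzz"):
            reachability_probability(fixture("series3"), "s", "zzz")

    def test_unreachable_target_gives_zero(self):
        net = build_network([("t", "s", 0.9)])
        assert reachability_probability(net, "s", "t") == 0.0


_probs = st.floats(min_value=0.01, max_value=1.0, allow_nan=False)


class TestClosedFormsUnderArbitraryProbabilities:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(p1=_probs, p2=_probs)
    def test_series_is_product(self, p1, p2):
        net = build_network([("s", "a", p1), ("a", "t", p2)])
        assert reachability_probability(net, "s", "t") == pytest.approx(
            p1 * p2, abs=1e-12
        )

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(p=st.tuples(_probs, _probs, _probs, _probs))
    def test_disjoint_routes_combine_by_inclusion_exclusion(self, p):
        p1, p2, p3, p4 = p
        net = build_network(
            [("s", "a", p1), ("a", "t", p2), ("s", "b", p3), ("b", "t", p4)]
        )
        expected = 1 - (1 - p1 * p2) * (1 - p3 * p4)
        assert reachability_probability(net, "s", "t") == pytest.approx(
            expected, abs=1e-12
        )


class TestInvariants:
    def test_oracle_equivalence_random_networks(self):
        rng = random.Random(21)
        for _ in range(60):
            net = random_network(rng, n_edges_range=(4, 12))
            nodes = sorted(net.nodes)
            s, t = rng.sample(nodes, 2)
            r = reachability_probability(net, s, t, check_conservation=True)
            assert abs(r - brute_force_reachability(net, s, t)) <= 1e-12

    def test_separator_invariance_greedy_vs_trivial(self):
        rng = random.Random(22)
        for _ in range(40):
            net = random_network(rng, n_edges_range=(4, 12))
            nodes = sorted(net.nodes)
            s, t = rng.sample(nodes, 2)
            greedy = reachability_probability(net, s, t)
            single = reachability_probability(
                net, s, t, sequence=trivial_separator_sequence(net, s, t)
            )
            assert abs(greedy - single) <= 1e-12

    def test_final_form_two_terms(self):
        net = prune_for_pair(fixture("fig2"), "1", "8")
        seq = greedy_separator_sequence(net, "1", "8")
        coeffs = {frozenset({"1"}): 1.0}
        for i, E in enumerate(seq.stages, start=1):
            stage = Stage.from_network(net, seq.separators[i - 1], seq.separators[i], E)
            coeffs = advance_stage(coeffs, stage, method="terms")
        assert set(coeffs) <= {frozenset({"8"}), frozenset()}
        assert sum(coeffs.values()) == pytest.approx(1.0)

    def test_monotone_in_edge_probability(self):
        rng = random.Random(23)
        for _ in range(15):
            net = random_network(rng, n_edges_range=(4, 10))
            nodes = sorted(net.nodes)
            s, t = rng.sample(nodes, 2)
            base = reachability_probability(net, s, t)
            e = rng.choice(net.edges)
            bumped = net.with_probabilities(
                {k: (min(1.0, v + 0.3) if k == e.index else v)
                 for k, v in net.edge_probability().items()}
            )
            assert reachability_probability(bumped, s, t) >= base - 1e-12

    def test_monotone_in_edge_addition(self):
        rng = random.Random(24)
        for _ in range(15):
            net = random_network(rng, n_nodes_range=(5, 7), n_edges_range=(4, 8))
            nodes = sorted(net.nodes)
            s, t = rng.sample(nodes, 2)
            base = reachability_probability(net, s, t)
            existing = {(e.source, e.target) for e in net.edges}
            candidates = [
                (u, v) for u in nodes for v in nodes
                if u != v and (u, v) not in existing and v != s and u != t
            ]
            if not candidates:
                continue
            u, v = rng.choice(candidates)
            bigger = build_network(
                [(e.source, e.target, e.p) for e in net.edges] + [(u, v, 0.7)],
                extra_nodes=nodes,
            )
            assert reachability_probability(bigger, s, t) >= base - 1e-12

    def test_certain_edges_degenerate_to_deterministic_reachability(self):
        rng = random.Random(25)
        for _ in range(15):
            net = random_network(rng, p_range=(1.0, 1.0))
            nodes = sorted(net.nodes)
            s, t = rng.sample(nodes, 2)
            det = maximal_deterministic(net)
            expected = float(chi(det, {s}, t, {e.index for e in det.edges}))
            assert reachability_probability(net, s, t) == pytest.approx(expected)

    def test_size_bound_during_stages(self):
        # during stage i+1 the open-term count never exceeds
        # 2^(|K_i| + |decided edges|), and the collapsed keys are subsets
        # of K_{i+1} plus the failure label
        rng = random.Random(26)
        for _ in range(10):
            net = random_network(rng, n_edges_range=(5, 10))
            nodes = sorted(net.nodes)
            s, t = rng.sample(nodes, 2)
            pruned = prune_for_pair(net, s, t)
            if not any(e.source == s for e in pruned.edges):
                continue
            seq = greedy_separator_sequence(pruned, s, t)
            coeffs = {frozenset({s}): 1.0}
            for i, E in enumerate(seq.stages, start=1):
                K_prev = seq.separators[i - 1]
                K_next = seq.separators[i]
                stage = Stage.from_network(pruned, K_prev, K_next, E)
                trace = []
                coeffs = advance_stage(coeffs, stage, trace=trace, method="terms")
                for step, (label, n_open, n_collapsed) in enumerate(trace):
                    decided = 0 if label.endswith("init") else step
                    assert n_open <= 2 ** (len(K_prev) + decided)
                    assert n_collapsed <= 2 ** len(K_next) + 1

    def test_terms_and_frontier_evaluators_agree(self):
        rng = random.Random(27)
        for _ in range(25):
            n = rng.randint(5, 8)
            nodes = [f"v{i}" for i in range(n)]
            pairs = set()
            while len(pairs) < rng.randint(5, 11):
                i, j = sorted(rng.sample(range(n), 2))
                pairs.add((nodes[i], nodes[j]))  # acyclic by index order
            net = build_network(
                [(u, v, rng.uniform(0.1, 1.0)) for u, v in sorted(pairs)],
                extra_nodes=nodes,
            )
            s, t = nodes[0], nodes[-1]
            pruned = prune_for_pair(net, s, t)
            if not any(e.source == s for e in pruned.edges):
                continue
            seq = greedy_separator_sequence(pruned, s, t)
            by_terms = {frozenset({s}): 1.0}
            by_frontier = {frozenset({s}): 1.0}
            for i, E in enumerate(seq.stages, start=1):
                stage = Stage.from_network(
                    pruned, seq.separators[i - 1], seq.separators[i], E
                )
                by_terms = advance_stage(by_terms, stage, method="terms")
                by_frontier = advance_stage(by_frontier, stage, method="frontier")
            for T in set(by_terms) | set(by_frontier):
                assert by_terms.get(T, 0.0) == pytest.approx(
                    by_frontier.get(T, 0.0), abs=1e-12
                )
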