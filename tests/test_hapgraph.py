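"""Edge weights, switch penalties, and the shortest-path haplotype solver."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import hapquant as hq
from hapquant import hapgraph
from hapquant.rates import PairScore
from hapquant.refset import ValidationError


class TestEdgeWeight:
    def test_unit_weight_at_one_minus_inv_e(self):
        assert hq.edge_weight(1 - 1 / math.e) == pytest.approx(1.0, abs=1e-9)

    def test_clamped_at_one(self):
        assert hq.edge_weight(1.0) == pytest.approx(
            1.0 / (-math.log(1e-9)), rel=1e-7
        )
        assert hq.edge_weight(1.0) == pytest.approx(0.0482549, abs=1e-6)

    def test_closed_form_at_09(self):
        assert hq.edge_weight(0.9) == pytest.approx(
            1.0 / (-math.log(0.1))
        )
        assert hq.edge_weight(0.9) == pytest.approx(0.4342945, abs=1e-6)

    def test_strictly_decreasing_and_nonnegative(self):
        grid = np.linspace(0.0, 1.0, 501)
        w = [hq.edge_weight(float(m)) for m in grid]
        assert all(v >= 0 for v in w)
        assert all(a > b for a, b in zip(w, w[1:]))

    @pytest.mark.parametrize("m", [-0.1, 1.1])
    def test_out_of_range_rejected(self, m):
        with pytest.raises(ValidationError):
            hq.edge_weight(m)


class TestSwitchCount:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (("A", "B"), ("A", "B"), 0),
            (("A", "B"), ("A", "C"), 1),
            (("A", "A"), ("B", "C"), 2),
            (("A", "A"), ("A", "B"), 1),
            (("A", "A"), ("A", "A"), 0),
            (("A", "B"), ("C", "D"), 2),
            (None, ("A", "B"), 0),
            (("A", "A"), None, 0),
        ],
    )
    def test_multiset_overlap(self, p1, p2, expected):
        assert hq.switch_count(p1, p2) == expected


def _graph(gene_states, penalty=hapgraph.DEFAULT_PENALTY):
    """gene_states: list of (gene, {pair: M})."""
    genes = [g for g, _ in gene_states]
    candidates = {g: list(states) for g, states in gene_states}
    scores = {
        g: [PairScore(g, p, m, 0.0) for p, m in states.items()]
        for g, states in gene_states
    }
    return hq.build_gene_graph(genes, candidates, scores, penalty=penalty)


class TestBuildGeneGraph:
    def test_single_gene_three_nodes_two_edges(self):
        g = _graph([("g1", {("A", "A"): 0.8})])
        nxg = hapgraph.to_networkx(g)
        assert nxg.number_of_nodes() == 3
        assert nxg.number_of_edges() == 2

    def test_two_genes_two_states_edge_weights_closed_form(self):
        states1 = {("A", "B"): 0.9, ("A", "C"): 0.8}
        states2 = {("A", "B"): 0.7, ("C", "C"): 0.6}
        g = _graph([("g1", states1), ("g2", states2)], penalty=0.01)
        for p1, m1 in states1.items():
            for p2, m2 in states2.items():
                expected = hq.edge_weight((m1 + m2) / 2) + 0.01 * hq.switch_count(
                    p1, p2
                )
                assert g.edge_cost("g1", p1, "g2", p2) == pytest.approx(expected)

    def test_wildcard_state_for_readless_gene(self):
        g = _graph([("g1", {("A", "A"): 0.9}), ("g2", {}), ("g3", {("A", "A"): 0.8})])
        assert g.states["g2"] == [None]
        # wildcard switches with nothing; edge rate falls back to neighbour M
        assert g.edge_cost("g1", ("A", "A"), "g2", None) == pytest.approx(
            hq.edge_weight(0.9)
        )
        calls = hq.best_haplotype_path(g)
        assert calls[1].wildcard and calls[1].pair is None

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            hq.build_gene_graph([], {}, {})

    def test_candidate_without_score_rejected(self):
        with pytest.raises(ValidationError):
            hq.build_gene_graph(["g1"], {"g1": [("A", "A")]}, {"g1": []})


class TestBestPath:
    def test_single_state_per_gene(self):
        g = _graph([("g1", {("A", "B"): 0.9}), ("g2", {("A", "B"): 0.7})])
        calls = hq.best_haplotype_path(g)
        assert [c.pair for c in calls] == [("A", "B"), ("A", "B")]

    def test_penalty_suppresses_isolated_switch(self):
        # middle gene marginally prefers (C, D), but two switches each side
        # cost more than its rate advantage
        states = {("A", "B"): 0.899, ("C", "D"): 0.9}
        g = _graph(
            [
                ("g1", {("A", "B"): 0.9}),
                ("g2", dict(states)),
                ("g3", {("A", "B"): 0.9}),
            ],
            penalty=0.01,
        )
        calls = hq.best_haplotype_path(g)
        assert [c.pair for c in calls] == [("A", "B")] * 3
        brute = hq.brute_force_path(g)
        assert [c.pair for c in brute] == [c.pair for c in calls]

    def test_no_penalty_reduces_to_per_gene_maximum(self):
        rng = np.random.default_rng(5)
        haps = ["A", "B", "C"]
        pairs = list(itertools.combinations_with_replacement(haps, 2))
        gene_states = []
        for i in range(6):
            ms = {p: float(m) for p, m in zip(pairs, rng.random(len(pairs)))}
            gene_states.append((f"g{i}", ms))
        g = _graph(gene_states, penalty=0.0)
        calls = hq.best_haplotype_path(g)
        for (gene, ms), call in zip(gene_states, calls):
            assert ms[call.pair] == pytest.approx(max(ms.values()))

    def test_huge_penalty_forces_constant_pair(self):
        gene_states = [
            ("g1", {("A", "B"): 0.9, ("A", "C"): 0.5}),
            ("g2", {("A", "B"): 0.2, ("B", "C"): 0.95}),
            ("g3", {("A", "B"): 0.8, ("A", "A"): 0.9}),
        ]
        g = _graph(gene_states, penalty=1e6)
        calls = hq.best_haplotype_path(g)
        assert [c.pair for c in calls] == [("A", "B")] * 3

    def test_dijkstra_equals_brute_force_and_networkx(self):
        """Randomised oracle: on >=100 small instances the DP path cost
        matches exhaustive enumeration and networkx Dijkstra."""
        rng = np.random.default_rng(123)
        haps = ["A", "B", "C", "D"]
        all_pairs = list(itertools.combinations_with_replacement(haps, 2))
        for trial in range(110):
            n_genes = int(rng.integers(1, 6))
            penalty = float(rng.choice([0.0, 0.0028, 0.05]))
            gene_states = []
            for i in range(n_genes):
                k = int(rng.integers(1, 5))
                chosen = rng.choice(len(all_pairs), size=k, replace=False)
                ms = {
                    all_pairs[int(c)]: float(rng.random()) for c in chosen
                }
                gene_states.append((f"g{i}", ms))
            g = _graph(gene_states, penalty=penalty)
            dp = hq.best_haplotype_path(g)
            brute = hq.brute_force_path(g)
            dp_cost = hapgraph.path_cost(g, [c.pair for c in dp])
            brute_cost = hapgraph.path_cost(g, [c.pair for c in brute])
            assert dp_cost == pytest.approx(brute_cost, abs=1e-12)
            nx_cost = nx.dijkstra_path_length(
                hapgraph.to_networkx(g), "__source__", "__sink__"
            )
            assert dp_cost == pytest.approx(nx_cost, abs=1e-9)

    def test_brute_force_refuses_oversized_instances(self):
        gene_states = [
            (f"g{i}", {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5})
            for i in range(20)
        ]
        g = _graph(gene_states)
        with pytest.raises(ValidationError, match="refused"):
            hq.brute_force_path(g, max_states=10**6)


class TestTieBreaks:
    def test_homozygous_preferred_at_exact_tie(self):
        for true_hap in ("A", "C"):
            pair_hom = (true_hap, true_hap)
            states = {pair_hom: 1.0}
            for other in "ABC":
                if other != true_hap:
                    states[tuple(sorted((true_hap, other)))] = 1.0
            g = _graph([("g1", dict(states)), ("g2", dict(states))])
            calls = hq.best_haplotype_path(g)
            assert [c.pair for c in calls] == [pair_hom, pair_hom]
            assert all(c.zygosity == "hom" for c in calls)

    def test_deterministic_under_candidate_permutation(self):
        states = {("A", "B"): 0.7, ("B", "C"): 0.7, ("A", "C"): 0.7}
        genes = ["g1", "g2", "g3"]
        base = None
        for perm in itertools.permutations(states):
            candidates = {g: list(perm) for g in genes}
            scores = {
                g: [PairScore(g, p, states[p], 0.0) for p in perm] for g in genes
            }
            g = hq.build_gene_graph(genes, candidates, scores)
            calls = tuple(c.pair for c in hq.best_haplotype_path(g))
            base = base or calls
            assert calls == base
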