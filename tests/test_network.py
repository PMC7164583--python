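"""Step distances, statistical-parsimony limit, network topology, origins."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    connection_limit_oracle,
    minimum_origins_oracle,
    parsimony_probability_oracle,
    steps_oracle,
)

from kdrevo.domain import AlignmentError, ConfigError
from kdrevo.network import (
    INTERMEDIATE,
    SAMPLED,
    ParsimonyNetwork,
    build_network,
    minimum_origins,
    mutational_steps,
    parsimony_connection_limit,
    parsimony_probability,
)


# ---------------------------------------------------------------------------
# mutational steps


def test_identical_sequences_are_zero_steps():
    assert mutational_steps("ACGTACGT", "ACGTACGT") == 0


def test_single_codon_change_is_one_step():
    a = "AAA" + "TTC" + "CCC"
    b = "AAA" + "TGC" + "CCC"
    assert mutational_steps(a, b) == 1


def test_snp_plus_gap_run_is_two_steps():
    a = "A" * 10 + "C" * 16 + "G" * 10
    b = "T" + "A" * 9 + "-" * 16 + "G" * 10
    assert mutational_steps(a, b) == 2
    assert mutational_steps(a, b, count_indels=False) == 1


def test_length_mismatch_is_alignment_error():
    with pytest.raises(AlignmentError):
        mutational_steps("ACGT", "ACG")


def _random_gapped(rng, length):
    seq = [rng.choice("ACGT") for _ in range(length)]
    for _ in range(rng.randint(0, 3)):
        start = rng.randrange(0, length - 6)
        for col in range(start, start + rng.randint(1, 6)):
            seq[col] = "-"
    return "".join(seq)


def test_steps_match_column_scan_oracle_on_random_pairs():
    rng = random.Random(7)
    for _ in range(300):
        a = _random_gapped(rng, 120)
        b = _random_gapped(rng, 120)
        assert mutational_steps(a, b) == steps_oracle(a, b)
        assert mutational_steps(a, b, False) == steps_oracle(a, b, False)
        assert mutational_steps(a, b) == mutational_steps(b, a)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT-", min_size=20, max_size=60))
def test_steps_zero_iff_identical_and_bounded_below_by_substitutions(seq):
    other = seq[::-1]
    d = mutational_steps(seq, other)
    assert d >= mutational_steps(seq, other, count_indels=False)
    assert (d == 0) == (seq == other)
    assert d == mutational_steps(other, seq)


# ---------------------------------------------------------------------------
# parsimony limit


def test_extreme_threshold_keeps_only_single_steps():
    for length in (100, 1000, 5000):
        assert parsimony_connection_limit(length, 0.999999) == 1


def test_limit_monotone_in_sequence_length():
    assert parsimony_connection_limit(4000) >= parsimony_connection_limit(400)
    limits = [parsimony_connection_limit(n) for n in (100, 500, 1000, 2100, 5000)]
    assert limits == sorted(limits)


def test_probability_matches_exact_arithmetic_oracle():
    for length in (100, 250, 500, 1000, 2100, 5000):
        for steps in (1, 2, 5, 10, 20):
            exact = float(parsimony_probability_oracle(steps, length))
            assert parsimony_probability(steps, length) == pytest.approx(exact, rel=1e-12)


def test_limit_matches_standalone_estimator():
    for length in (100, 250, 500, 1000, 2100, 5000):
        for threshold in (0.90, 0.95, 0.99):
            assert parsimony_connection_limit(length, threshold) == connection_limit_oracle(
                length, threshold
            )


def test_bad_threshold_is_config_error():
    with pytest.raises(ConfigError):
        parsimony_connection_limit(100, 1.0)
    with pytest.raises(ConfigError):
        parsimony_connection_limit(0, 0.95)


# ---------------------------------------------------------------------------
# network construction


def _seqs_from_steps(base_len, edits):
    """Build sequences at controlled distances by editing distinct columns."""
    base = "A" * base_len
    out = {"P1": base}
    col = 0
    for name, d in edits:
        seq = list(base)
        for _ in range(d):
            seq[col] = "C"
            col += 1
        out[name] = "".join(seq)
    return out


def test_one_step_pair_is_a_single_edge():
    seqs = _seqs_from_steps(50, [("P2", 1)])
    net = build_network(seqs, limit=10)
    assert set(net.graph.nodes) == {"P1", "P2"}
    assert net.graph.has_edge("P1", "P2")


def test_multi_step_connection_realized_as_intermediate_chain():
    seqs = _seqs_from_steps(50, [("P2", 3)])
    net = build_network(seqs, limit=10)
    assert len(net.intermediate_nodes) == 2
    assert nx.shortest_path_length(net.graph, "P1", "P2") == 3
    for node in net.intermediate_nodes:
        assert net.graph.degree[node] >= 2


def test_pairs_beyond_the_limit_stay_in_separate_components():
    seqs = _seqs_from_steps(50, [("P2", 6)])
    net = build_network(seqs, limit=5)
    assert len(net.components()) == 2


def test_chain_and_star_topologies_are_reproduced():
    # chain: P1 -1- P2 -1- P3 (P1..P3 at 2 steps)
    base = "A" * 40
    chain = {"P1": base, "P2": "C" + base[1:], "P3": "CC" + base[2:]}
    net = build_network(chain, limit=10)
    assert net.graph.degree["P2"] == 2
    assert nx.shortest_path_length(net.graph, "P1", "P3") == 2
    # the spanning structure agrees with a minimum spanning tree on the
    # step matrix for tree-realizable inputs
    assert len(net.graph.edges) == len(net.graph.nodes) - 1

    star = {
        "P1": base,
        "P2": "C" + base[1:],
        "P3": base[:10] + "C" + base[11:],
        "P4": base[:20] + "C" + base[21:],
    }
    net = build_network(star, limit=10)
    assert net.graph.degree["P1"] == 3


def test_node_count_invariant(study_result):
    net = study_result.network
    realized = sum(
        1 for n, d in net.graph.nodes(data=True) if d["kind"] == INTERMEDIATE
    )
    assert len(net.graph.nodes) == len(net.sampled_nodes) + realized
    # every sampled pattern is a node
    assert set(net.ids) <= set(net.graph.nodes)


def test_network_is_deterministic(study_dataset):
    from kdrevo.pipeline import analyze

    ds = study_dataset
    r1 = analyze(ds.sequences, ds.aspcr, ds.metadata)
    r2 = analyze(ds.sequences, ds.aspcr, ds.metadata)
    assert nx.utils.graphs_equal(r1.network.graph, r2.network.graph)


# ---------------------------------------------------------------------------
# minimum origins


def _net_from_edges(edges, kinds):
    g = nx.Graph()
    for n, kind in kinds.items():
        g.add_node(n, kind=kind, count=0)
    g.add_edges_from(edges)
    return ParsimonyNetwork(g, 10, [n for n, k in kinds.items() if k == SAMPLED])


def test_alternating_path_needs_two_origins():
    # S - C - S - C: the two derived nodes are separated by a susceptible one
    kinds = {n: SAMPLED for n in "abcd"}
    net = _net_from_edges([("a", "b"), ("b", "c"), ("c", "d")], kinds)
    states = {"a": "S", "b": "C", "c": "S", "d": "C"}
    assert minimum_origins(net, states, "C") == 2


def test_single_clade_is_one_origin():
    kinds = {"hub": INTERMEDIATE, "t1": SAMPLED, "t2": SAMPLED, "t3": SAMPLED}
    net = _net_from_edges([("hub", "t1"), ("hub", "t2"), ("hub", "t3")], kinds)
    states = {"t1": "C", "t2": "C", "t3": "C"}
    assert minimum_origins(net, states, "C") == 1


def test_no_derived_nodes_is_zero_origins():
    kinds = {"a": SAMPLED, "b": SAMPLED}
    net = _net_from_edges([("a", "b")], kinds)
    assert minimum_origins(net, {"a": "S", "b": "S"}, "C") == 0


def test_origins_match_exhaustive_search_on_small_graphs():
    """Closed form equals brute force over all intermediate assignments on
    random connected graphs of at most 12 nodes."""
    rng = random.Random(13)
    for trial in range(150):
        n = rng.randint(2, 12)
        nodes = [f"n{i}" for i in range(n)]
        # random spanning tree plus a few extra edges
        edges = [(nodes[i], nodes[rng.randrange(i)]) for i in range(1, n)]
        for _ in range(rng.randint(0, 3)):
            a, b = rng.sample(nodes, 2)
            edges.append((a, b))
        n_free = rng.randint(0, min(8, n - 1))
        free = nodes[:n_free]
        fixed = {m: rng.choice(["S", "C"]) for m in nodes[n_free:]}
        kinds = {m: (INTERMEDIATE if m in free else SAMPLED) for m in nodes}
        net = _net_from_edges(edges, kinds)
        expected = minimum_origins_oracle(edges, fixed, free, "C")
        assert minimum_origins(net, fixed, "C") == expected
        # never exceeds the count of derived components among sampled nodes
        sampled_derived = {m for m, s in fixed.items() if s == "C"}
        if sampled_derived:
            sub = net.graph.subgraph(sampled_derived)
            assert minimum_origins(net, fixed, "C") <= nx.number_connected_components(sub)
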