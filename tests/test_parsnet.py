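"""Network construction and connection-limit behaviour.

The reference ("oracle") network builder used here is an independent,
deliberately naive implementation: plain dicts, breadth-first searches and
whole-component rescans instead of union-find and networkx, with the same
join order and tie rules.  Small cases are compared against it exhaustively.
"""

import itertools
import random

import networkx as nx
import pytest

from ribopool.catalog import column_distance
from ribopool.parsnet import (
    Haplotype,
    NetworkConfig,
    NetworkConfigError,
    annotate_node_weights,
    build_network,
    haplotypes_from_tables,
    parsimony_connection_limit,
    probability_of_parsimony,
)


# ---------------------------------------------------------------------------
# Oracle
# ---------------------------------------------------------------------------

def oracle_network(haps, limit):
    """Naive reference construction: adjacency dict keyed by state tuples."""
    nodes = {tuple(sorted(h.states.items())): h for h in haps}
    adj = {k: set() for k in nodes}
    weight = {k: h.total_weight for k, h in nodes.items()}
    name = {k: h.name for k, h in nodes.items()}

    def dist(a, b):
        return sum(1 for (p, x), (_, y) in zip(a, b) if x != y)

    def bfs_component(start):
        seen, queue = {start}, [start]
        while queue:
            cur = queue.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        return seen

    sampled = list(nodes)
    for a, b in itertools.combinations(sampled, 2):
        if dist(a, b) == 1:
            adj[a].add(b)
            adj[b].add(a)
    iv = 0
    for d in range(2, limit + 1):
        while True:
            cands = [
                (a, b)
                for a, b in itertools.combinations(sampled, 2)
                if dist(a, b) == d and b not in bfs_component(a)
            ]
            if not cands:
                break

            def rank(k):
                return (-weight[k], -len(adj[k]), name[k])

            a, b = min(cands, key=lambda ab: tuple(sorted((rank(ab[0]), rank(ab[1])))))
            a, b = sorted((a, b), key=lambda k: name[k])
            diffs = sorted(p for (p, x), (q, y) in zip(a, b) if x != y)
            prev = a
            current = dict(a)
            for p in diffs[:-1]:
                current[p] = dict(b)[p]
                key = tuple(sorted(current.items()))
                if key not in adj:
                    iv += 1
                    adj[key] = set()
                    weight[key] = 0
                    name[key] = f"iv{iv}"
                adj[prev].add(key)
                adj[key].add(prev)
                prev = key
            adj[prev].add(b)
            adj[b].add(prev)
    return nodes, adj, name


def oracle_summary(haps, limit):
    nodes, adj, name = oracle_network(haps, limit)
    G = nx.Graph()
    G.add_nodes_from(adj)
    for k, vs in adj.items():
        for v in vs:
            G.add_edge(k, v)
    comp_of = {}
    for i, comp in enumerate(nx.connected_components(G)):
        for k in comp:
            comp_of[k] = i
    partition = frozenset(
        frozenset(name[k] for k in comp if k in nodes)
        for comp in nx.connected_components(G)
        if any(k in nodes for k in comp)
    )
    sampled_names = {name[k]: k for k in nodes}
    paths = {}
    for a, b in itertools.combinations(sorted(sampled_names), 2):
        ka, kb = sampled_names[a], sampled_names[b]
        if comp_of[ka] == comp_of[kb]:
            paths[(a, b)] = nx.shortest_path_length(G, ka, kb)
    return partition, paths


def built_summary(net):
    sampled = [n for n, d in net.nodes(data=True) if d["sampled"]]
    partition = frozenset(
        frozenset(n for n in comp if n in sampled)
        for comp in nx.connected_components(net)
        if any(n in sampled for n in comp)
    )
    paths = {}
    for a, b in itertools.combinations(sorted(sampled), 2):
        if net.nodes[a]["component"] == net.nodes[b]["component"]:
            paths[(a, b)] = nx.shortest_path_length(net, a, b)
    return partition, paths


# ---------------------------------------------------------------------------
# Connection limit
# ---------------------------------------------------------------------------

class TestConnectionLimit:
    def test_zero_differences_are_certainly_parsimonious(self):
        assert probability_of_parsimony(0, 330) == 1.0

    def test_single_step_accepted_at_95_for_amplicon_lengths(self):
        for length in (130, 330, 600):
            assert parsimony_connection_limit(length, 0.95) >= 1

    def test_limit_nondecreasing_in_length(self):
        limits = [
            parsimony_connection_limit(m, 0.95)
            for m in (50, 100, 200, 330, 500, 800, 1200)
        ]
        assert limits == sorted(limits)

    def test_limit_nonincreasing_in_confidence(self):
        l90 = parsimony_connection_limit(330, 0.90)
        l95 = parsimony_connection_limit(330, 0.95)
        l99 = parsimony_connection_limit(330, 0.99)
        assert l99 <= l95 <= l90

    def test_parsimony_probability_decreases_in_steps(self):
        probs = [probability_of_parsimony(j, 330) for j in range(0, 12)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_invalid_confidence_rejected(self):
        with pytest.raises(NetworkConfigError):
            parsimony_connection_limit(330, 1.5)
        with pytest.raises(NetworkConfigError):
            NetworkConfig(confidence=0.0)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _hap(matrix, name, reads=5000, weights=None):
    return Haplotype(
        name=name,
        states=matrix.states_of(name),
        total_reads=reads,
        weights=weights or {},
    )


class TestBuildNetwork:
    def test_distance_one_pair_is_a_single_edge(self, matrix):
        net = build_network(
            [_hap(matrix, "As1"), _hap(matrix, "Al/As2")], sequence_length=330
        )
        assert set(net.nodes) == {"As1", "Al/As2"}
        assert net.number_of_edges() == 1

    def test_stepwise_substitution_series_forms_path(self, matrix):
        # Al/As2 = As1 + {130:C}; As5 = Al/As2 + {175:T}
        net = build_network(
            [_hap(matrix, n) for n in ("As1", "Al/As2", "As5")], sequence_length=330
        )
        assert sorted(net.edges()) == sorted(
            [("As1", "Al/As2"), ("Al/As2", "As5")]
        ) or set(map(frozenset, net.edges())) == {
            frozenset({"As1", "Al/As2"}),
            frozenset({"Al/As2", "As5"}),
        }

    def test_every_edge_is_a_unit_step(self, matrix):
        net = build_network(
            [_hap(matrix, n) for n in matrix.names], sequence_length=330
        )
        for u, v in net.edges():
            assert (
                column_distance(net.nodes[u]["states"], net.nodes[v]["states"]) == 1
            )

    def test_divergent_family_disconnected_on_full_catalog(self, matrix):
        net = build_network(
            [_hap(matrix, n) for n in matrix.names], sequence_length=330
        )
        comp = {n: d["component"] for n, d in net.nodes(data=True)}
        non_c = {n for n in matrix.names if matrix.family[n] != "C"}
        assert len({comp[n] for n in non_c}) == 1
        assert comp["C-genome-related"] not in {comp[n] for n in non_c}

    def test_intermediate_nodes_have_degree_at_least_two(self, matrix):
        net = build_network(
            [_hap(matrix, n) for n in matrix.names], sequence_length=330
        )
        for n, d in net.nodes(data=True):
            if not d["sampled"]:
                assert net.degree(n) >= 2

    def test_within_limit_pairs_share_a_component(self, matrix):
        # haplotype pairs within the connection limit must end up connected
        # (possibly transitively, so path lengths may exceed the pairwise
        # distance); unit-distance pairs must be directly adjacent
        net = build_network(
            [_hap(matrix, n) for n in matrix.names], sequence_length=330
        )
        limit = net.graph["connection_limit"]
        sampled = [n for n, d in net.nodes(data=True) if d["sampled"]]
        for a, b in itertools.combinations(sampled, 2):
            d = column_distance(net.nodes[a]["states"], net.nodes[b]["states"])
            if d <= limit:
                assert net.nodes[a]["component"] == net.nodes[b]["component"]
            if d == 1:
                assert net.has_edge(a, b)

    def test_min_reads_admission_is_inclusive(self, matrix):
        haps = [_hap(matrix, "As1", reads=10), _hap(matrix, "Al/As2", reads=9)]
        net = build_network(haps, NetworkConfig(min_reads=10), 330)
        assert set(net.nodes) == {"As1"}

    def test_raising_min_reads_never_adds_nodes(self, matrix):
        haps = [_hap(matrix, n, reads=50 * (i + 1)) for i, n in enumerate(matrix.names)]
        prev = None
        for threshold in (10, 100, 300, 600):
            net = build_network(haps, NetworkConfig(min_reads=threshold), 330)
            nodes = {n for n, d in net.nodes(data=True) if d["sampled"]}
            if prev is not None:
                assert nodes <= prev
            prev = nodes

    def test_lowering_confidence_never_splits_components(self, matrix):
        haps = [_hap(matrix, n) for n in matrix.names]
        strict = build_network(haps, NetworkConfig(confidence=0.99), 330)
        loose = build_network(haps, NetworkConfig(confidence=0.90), 330)

        def partition(net):
            comp = {}
            for n, d in net.nodes(data=True):
                if d["sampled"]:
                    comp.setdefault(d["component"], set()).add(n)
            return list(comp.values())

        for strict_comp in partition(strict):
            # every strict component must sit inside one loose component
            assert any(strict_comp <= loose_comp for loose_comp in partition(loose))

    def test_empty_admitted_set_gives_empty_network(self, matrix):
        net = build_network(
            [_hap(matrix, "As1", reads=1)], NetworkConfig(min_reads=10), 330
        )
        assert net.number_of_nodes() == 0

    def test_matches_oracle_on_small_subsets(self, matrix):
        rng = random.Random(4)
        names = list(matrix.names)
        subsets = [rng.sample(names, rng.randint(2, 6)) for _ in range(12)]
        subsets.append(["As1", "Al/As2", "As5"])
        subsets.append(["D", "Am/Amp", "Aby4", "As1"])
        for subset in subsets:
            haps = [_hap(matrix, n) for n in subset]
            net = build_network(haps, sequence_length=330)
            limit = net.graph["connection_limit"]
            assert built_summary(net) == oracle_summary(haps, limit)

    def test_deterministic_construction(self, matrix):
        haps = [_hap(matrix, n) for n in matrix.names]
        a = build_network(haps, sequence_length=330)
        b = build_network(list(reversed(haps)), sequence_length=330)
        assert sorted(map(tuple, map(sorted, a.edges()))) == sorted(
            map(tuple, map(sorted, b.edges()))
        )


class TestWeights:
    def test_node_weights_collect_major_percents_per_accession(
        self, matrix, published_tables
    ):
        byz = [published_tables[k] for k in ("K-13351", "K-1785", "K-15252")]
        haps = haplotypes_from_tables(byz, matrix)
        net = build_network(haps, NetworkConfig(), 330)
        annotate_node_weights(net, byz)
        assert net.nodes["D"]["weights"] == {
            "K-13351": 43,
            "K-1785": 42,
            "K-15252": 40,
        }
        assert net.nodes["D"]["weight"] == 125.0

    def test_single_accession_node_weight_equals_its_percent(
        self, matrix, published_tables
    ):
        byz = [published_tables[k] for k in ("K-13351", "K-15252")]
        net = build_network(haplotypes_from_tables(byz, matrix), NetworkConfig(), 330)
        annotate_node_weights(net, byz)
        assert net.nodes["Aby3"]["weights"] == {"K-15252": 7}

    def test_intermediates_carry_zero_weight(self, matrix, published_tables):
        tables = list(published_tables.values())
        net = build_network(
            haplotypes_from_tables(tables, matrix), NetworkConfig(), 330
        )
        annotate_node_weights(net, tables)
        for n, d in net.nodes(data=True):
            if not d["sampled"]:
                assert d["weight"] == 0.0


def test_graphml_and_edge_list_round_trip(tmp_path, matrix):
    from ribopool.parsnet import write_edge_tsv, write_graphml

    net = build_network(
        [_hap(matrix, n) for n in ("As1", "Al/As2", "As5")], sequence_length=330
    )
    gml = tmp_path / "net.graphml"
    write_graphml(net, gml)
    loaded = nx.read_graphml(gml)
    assert set(loaded.nodes) == set(net.nodes)
    assert loaded.number_of_edges() == net.number_of_edges()
    tsv = tmp_path / "edges.tsv"
    write_edge_tsv(net, tsv)
    assert len(tsv.read_text().strip().splitlines()) == net.number_of_edges() + 1
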