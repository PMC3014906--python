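import itertools

import networkx as nx
import numpy as np
import pytest

from mtlineage import panels
from mtlineage.core import HaplotypeMotif, SampleRecord, Variant, hvsi_window
from mtlineage.network import (
    HaploNetwork,
    MJParams,
    MultistateError,
    _msn_edges,
    export_network,
    median_joining,
    minimum_spanning_network,
    pairwise_distance,
    read_network,
)
from conftest import as_record


def motif(tokens, label=None):
    return HaplotypeMotif.from_tokens(tokens, hvsi_window(), label)


def records(*token_lists):
    return [as_record(motif(toks, f"m{i}"), f"m{i}") for i, toks in enumerate(token_lists)]


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_msn(token_sets):
    """Union of all minimum spanning trees, by explicit enumeration."""
    keys = [frozenset(t) for t in token_sets]
    idx = list(range(len(keys)))
    all_edges = [
        (i, j, len(keys[i] ^ keys[j])) for i, j in itertools.combinations(idx, 2)
    ]
    best = None
    union = set()
    for combo in itertools.combinations(all_edges, len(idx) - 1):
        g = nx.Graph()
        g.add_nodes_from(idx)
        g.add_weighted_edges_from(combo)
        if not nx.is_connected(g):
            continue
        total = sum(w for _, _, w in combo)
        if best is None or total < best - 1e-9:
            best = total
            union = {frozenset((keys[i], keys[j])) for i, j, _ in combo}
        elif abs(total - best) < 1e-9:
            union |= {frozenset((keys[i], keys[j])) for i, j, _ in combo}
    return best, union


def median_closure(token_sets, cap=4000):
    """All median vectors reachable from the sampled set (fixpoint)."""
    closure = {frozenset(t) for t in token_sets}
    while True:
        new = set()
        for a, b, c in itertools.combinations(closure, 3):
            counts = {}
            for s in (a, b, c):
                for t in s:
                    counts[t] = counts.get(t, 0) + 1
            m = frozenset(t for t, k in counts.items() if k >= 2)
            if m not in closure:
                new.add(m)
        if not new:
            return closure
        closure |= new
        if len(closure) > cap:
            raise RuntimeError("closure blew up")


def brute_force_steiner(token_sets, closure):
    """Minimal MST length over sampled nodes plus any subset of medians."""
    sampled = {frozenset(t) for t in token_sets}
    medians = sorted(closure - sampled, key=lambda s: tuple(sorted(s)))
    best = None
    for r in range(len(medians) + 1):
        for combo in itertools.combinations(medians, r):
            nodes = list(sampled) + list(combo)
            g = nx.Graph()
            for a, b in itertools.combinations(nodes, 2):
                g.add_edge(a, b, weight=len(a ^ b))
            total = sum(
                d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True)
            ) if len(nodes) > 1 else 0
            if best is None or total < best:
                best = total
    return best


def mst_length(nodes):
    if len(nodes) <= 1:
        return 0.0
    g = nx.Graph()
    for a, b in itertools.combinations(nodes, 2):
        g.add_edge(a, b, weight=len(a ^ b))
    return sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))


def steiner_value(token_sets, nodes):
    """Shortest median-augmented spanning structure available within
    ``nodes`` (minimum over subsets of the non-sampled nodes)."""
    sampled = {frozenset(t) for t in token_sets}
    return brute_force_steiner(token_sets, set(nodes) | sampled)


def random_token_sets(rng, n_motifs, n_sites):
    positions = rng.choice(
        np.arange(16045, 16363), size=n_sites, replace=False
    )
    window = hvsi_window()
    tokens = []
    for p in sorted(int(x) for x in positions):
        ref = window.base_at(p)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        tokens.append(f"{p}{alt}")
    out = set()
    while len(out) < n_motifs:
        out.add(frozenset(t for t in tokens if rng.random() < 0.5))
    return [sorted(s) for s in out]


# ---------------------------------------------------------------------------


class TestPairwiseDistance:
    def test_identical_zero(self, founder_c):
        assert pairwise_distance(founder_c, founder_c) == 0

    def test_bot01_vs_bot03_one(self, botocudo_resolved):
        bot = {r.id: r.motif for r in botocudo_resolved}
        assert pairwise_distance(bot["Bot01"], bot["Bot03"]) == 1

    def test_mg31_vs_founder_four(self, queix, founder_c):
        mg31 = next(r for r in queix if r.id == "MG31")
        assert pairwise_distance(mg31.motif, founder_c) == 4

    def test_window_mismatch_rejected(self, founder_c):
        from mtlineage.core import reference_window

        other = HaplotypeMotif(reference_window(), ())
        with pytest.raises(Exception):
            pairwise_distance(founder_c, other)

    def test_site_weights(self, founder_c, botocudo_resolved):
        bot03 = next(r for r in botocudo_resolved if r.id == "Bot03").motif
        assert pairwise_distance(founder_c, bot03, weights={16051: 2.5}) == 2.5


class TestMinimumSpanningNetwork:
    def test_two_motifs_single_edge(self):
        net = minimum_spanning_network(records(["16051G"], ["16051G", "16223T"]))
        assert net.graph.number_of_edges() == 1

    def test_three_equidistant_motifs_triangle(self):
        recs = records(["16051G"], ["16223T"], ["16298C"])
        net = minimum_spanning_network(recs)
        assert net.graph.number_of_edges() == 3  # all tie edges kept
        _, union = brute_force_msn([r.motif.token_set() for r in recs])
        got = {frozenset((a, b)) for a, b in net.graph.edges}
        assert got == union

    def test_botocudo_c_motifs_match_exhaustive_mst_union(self, botocudo_resolved):
        net = minimum_spanning_network(botocudo_resolved)
        _, union = brute_force_msn([r.motif.token_set() for r in botocudo_resolved])
        got = {frozenset((a, b)) for a, b in net.graph.edges}
        assert got == union

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            sets = random_token_sets(rng, int(rng.integers(3, 6)), 6)
            net = minimum_spanning_network(
                [as_record(motif(s, f"r{i}"), f"r{i}") for i, s in enumerate(sets)]
            )
            _, union = brute_force_msn(sets)
            got = {frozenset((a, b)) for a, b in net.graph.edges}
            assert got == union

    def test_duplicates_collapsed_with_summed_frequency(self):
        recs = [
            as_record(motif(["16051G"], "a"), "a", count=2),
            as_record(motif(["16051G"], "b"), "b", count=3),
        ]
        net = minimum_spanning_network(recs)
        (node,) = net.nodes()
        assert net.graph.nodes[node]["frequency"] == 5
        assert net.graph.nodes[node]["labels"] == ("a", "b")

    def test_epsilon_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            sets = random_token_sets(rng, 5, 7)
            keys = [frozenset(s) for s in sets]
            previous = None
            for eps in (0, 1, 2):
                edges = {
                    frozenset((a, b)) for a, b, _ in _msn_edges(keys, None, eps)
                }
                if previous is not None:
                    assert previous <= edges
                previous = edges


class TestMedianJoining:
    def test_single_motif(self):
        net = median_joining(records(["16051G"]))
        assert len(net.graph) == 1 and net.graph.number_of_edges() == 0

    def test_three_singletons_star_median(self):
        recs = records(["16051G"], ["16223T"], ["16298C"])
        net = median_joining(recs)
        medians = net.median_nodes()
        assert medians == [frozenset()]  # empty motif = shared background
        assert net.graph.degree(frozenset()) == 3
        assert net.total_length() == 3  # brute-force Steiner minimum
        closure = median_closure([r.motif.token_set() for r in recs])
        assert brute_force_steiner([r.motif.token_set() for r in recs], closure) == 3

    def test_contains_minimum_spanning_structure(self, botocudo_resolved):
        net = median_joining(botocudo_resolved)
        sampled = [frozenset(r.motif.token_set()) for r in botocudo_resolved]
        assert set(sampled) <= set(net.graph.nodes)
        assert net.is_connected()
        assert steiner_value(sampled, net.graph.nodes) <= mst_length(sampled)

    def test_matches_brute_force_minimum_on_small_instances(self):
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(12):
            sets = random_token_sets(rng, int(rng.integers(3, 7)), int(rng.integers(4, 9)))
            try:
                closure = median_closure(sets)
            except RuntimeError:
                continue
            if len(closure) - len(sets) > 10:
                continue
            oracle = brute_force_steiner(sets, closure)
            net = median_joining(
                [as_record(motif(s, f"r{i}"), f"r{i}") for i, s in enumerate(sets)]
            )
            assert steiner_value(sets, net.graph.nodes) == oracle
            checked += 1
        assert checked >= 5

    def test_figure_topology_founder_is_internal_cut_node(self):
        net = median_joining(panels.figure_c_records())
        founder = frozenset({"16223T", "16298C", "16325C", "16327T"})
        assert founder in net.graph.nodes
        assert net.graph.degree(founder) >= 3
        assert founder in set(nx.articulation_points(net.graph))

    def test_epsilon_zero_medians_all_useful(self):
        recs = records(
            ["16051G", "16223T"], ["16051G", "16298C"], ["16223T", "16298C"]
        )
        net = median_joining(recs)
        sampled = set(frozenset(r.motif.token_set()) for r in recs)
        for m in net.median_nodes():
            g = net.graph.copy()
            g.remove_node(m)
            dist_before = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
            still_ok = True
            for s, t in itertools.combinations(sorted(sampled, key=sorted), 2):
                if not nx.has_path(g, s, t):
                    still_ok = False
                    break
                if nx.dijkstra_path_length(g, s, t, weight="weight") > dist_before[s][t]:
                    still_ok = False
                    break
            assert not still_ok  # removing any median breaks a shortest path

    def test_multistate_site_rejected(self):
        window = hvsi_window()
        a = HaplotypeMotif(window, (Variant(16223, "C", "T"),), "a")
        b = HaplotypeMotif(window, (Variant(16223, "C", "A"),), "b")
        with pytest.raises(MultistateError):
            median_joining([as_record(a, "a"), as_record(b, "b")])


class TestExport:
    def test_round_trip(self, tmp_path, botocudo_resolved):
        net = median_joining(botocudo_resolved)
        export_network(net, tmp_path / "net")
        back = read_network(tmp_path / "net")
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert len(back.graph) == len(net.graph)
        for a, b in net.graph.edges:
            assert back.edge_weight(a, b) == net.edge_weight(a, b)
        for n in net.graph.nodes:
            assert back.graph.nodes[n] == net.graph.nodes[n]

    def test_gml_export(self, tmp_path, botocudo_resolved):
        net = minimum_spanning_network(botocudo_resolved)
        (path,) = export_network(net, tmp_path / "net", fmt="gml")
        g = nx.read_gml(str(path))
        assert len(g) == len(net.graph)

    def test_unknown_format_rejected(self, tmp_path, botocudo_resolved):
        from mtlineage.core import InputError

        net = minimum_spanning_network(botocudo_resolved)
        with pytest.raises(InputError):
            export_network(net, tmp_path / "net", fmt="dot")
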