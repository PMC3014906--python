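"""Minimum-spanning and median-joining haplotype networks.

Motifs are treated as binary characters (reference allele vs one derived
allele per varied position); multistate sites raise an explicit error.  The
median of three nodes is the per-site majority vector.  The network is the
epsilon-relaxed minimum spanning network over sampled motifs plus the
median vectors added by the usual iterate-until-stable scheme, followed by
removal of unsampled medians that support no shortest path.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .core import HaplotypeMotif, InputError, ParseError, SampleRecord

__all__ = [
    "MJParams",
    "HaploNetwork",
    "MultistateError",
    "pairwise_distance",
    "minimum_spanning_network",
    "median_joining",
    "export_network",
    "read_network",
]


class MultistateError(InputError):
    """A position carries more than one derived allele across the motifs."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, nodes: int):
        super().__init__(message)
        self.nodes = nodes


@dataclass(frozen=True)
class MJParams:
    epsilon: int = 0
    weights: Mapping[int, float] | None = None
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise InputError("epsilon must be >= 0")
        if self.weights and any(w <= 0 for w in self.weights.values()):
            raise InputError("site weights must be positive")


@dataclass
class HaploNetwork:
    """Nodes are frozensets of variant tokens; attributes carry labels,
    count-weighted frequency and the median flag."""

    graph: nx.Graph
    window: tuple[int, int]

    def nodes(self) -> list[frozenset[str]]:
        return sorted(self.graph.nodes, key=_node_key)

    def sampled_nodes(self) -> list[frozenset[str]]:
        return [n for n in self.nodes() if not self.graph.nodes[n]["is_median"]]

    def median_nodes(self) -> list[frozenset[str]]:
        return [n for n in self.nodes() if self.graph.nodes[n]["is_median"]]

    def edge_weight(self, a: frozenset[str], b: frozenset[str]) -> float:
        return self.graph.edges[a, b]["weight"]

    def total_length(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def is_connected(self) -> bool:
        return len(self.graph) == 0 or nx.is_connected(self.graph)


def _node_key(tokens: frozenset[str]) -> tuple:
    return tuple(sorted(tokens))


def _token_position(token: str) -> int:
    return int(re.match(r"\d+", token).group())


def _weight_of(position: int, weights: Mapping[int, float] | None) -> float:
    return 1.0 if not weights else weights.get(position, 1.0)


def pairwise_distance(
    a: HaplotypeMotif,
    b: HaplotypeMotif,
    weights: Mapping[int, float] | None = None,
) -> float:
    """Weighted count of positions in the symmetric difference of the two
    variant sets (poly-C length variants excluded)."""
    if (a.window.start, a.window.end) != (b.window.start, b.window.end):
        raise InputError("motifs on different windows")
    ta = a.without_length_variants().token_set()
    tb = b.without_length_variants().token_set()
    positions = {_token_position(t) for t in ta ^ tb}
    return sum(_weight_of(p, weights) for p in positions)


def _token_distance(
    a: frozenset[str], b: frozenset[str], weights: Mapping[int, float] | None
) -> float:
    positions = {_token_position(t) for t in a ^ b}
    return sum(_weight_of(p, weights) for p in positions)


def _collapse(
    records: Sequence[SampleRecord],
) -> tuple[dict[frozenset[str], dict], tuple[int, int]]:
    """Collapse duplicate motifs, summing frequencies and pooling labels."""
    if not records:
        raise InputError("at least one motif required")
    windows = {
        (r.motif.window.start, r.motif.window.end) for r in records if r.resolved
    }
    if len(windows) != 1:
        raise InputError("all motifs must share one window")
    unresolved = [r.id for r in records if not r.resolved]
    if unresolved:
        raise InputError(f"unresolved motifs cannot be placed in a network: {unresolved}")

    allele_at: dict[int, str] = {}
    nodes: dict[frozenset[str], dict] = {}
    for r in records:
        motif = r.motif.without_length_variants()
        for v in motif.variants:
            seen = allele_at.setdefault(v.position, v.alt)
            if seen != v.alt:
                raise MultistateError(
                    f"position {v.position} carries alleles {seen} and {v.alt}; "
                    "multistate sites are not supported"
                )
        key = motif.token_set()
        entry = nodes.setdefault(key, {"labels": [], "frequency": 0, "is_median": False})
        entry["labels"].append(r.id)
        entry["frequency"] += r.count
    for entry in nodes.values():
        entry["labels"] = tuple(sorted(entry["labels"]))
    return nodes, windows.pop()


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _msn_edges(
    keys: Sequence[frozenset[str]],
    weights: Mapping[int, float] | None,
    epsilon: float,
) -> list[tuple[frozenset[str], frozenset[str], float]]:
    """Epsilon-relaxed minimum spanning network edge list.

    An edge {u, v} is kept iff its weight is within ``epsilon`` of the
    minimax connection cost of u and v (the largest edge on the bottleneck
    path between them, read off a minimum spanning tree).  With epsilon 0
    this is exactly the union of all minimum spanning trees; the edge set
    grows monotonically with epsilon.
    """
    keys = sorted(keys, key=_node_key)
    if len(keys) <= 1:
        return []
    g = nx.Graph()
    for a, b in itertools.combinations(keys, 2):
        g.add_edge(a, b, weight=_token_distance(a, b, weights))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    edges: list[tuple[frozenset[str], frozenset[str], float]] = []
    for root in keys:
        # minimax distance from root to all others along the (unique) MST path
        minimax: dict[frozenset[str], float] = {root: 0.0}
        stack = [root]
        while stack:
            u = stack.pop()
            for v in mst.neighbors(u):
                if v not in minimax:
                    minimax[v] = max(minimax[u], mst.edges[u, v]["weight"])
                    stack.append(v)
        for other in keys:
            if _node_key(other) <= _node_key(root):
                continue
            d = g.edges[root, other]["weight"]
            if d <= minimax[other] + epsilon:
                edges.append((root, other, d))
    return edges


def _build_network(
    node_attrs: Mapping[frozenset[str], dict],
    window: tuple[int, int],
    weights: Mapping[int, float] | None,
    epsilon: float,
) -> HaploNetwork:
    g = nx.Graph()
    for key in sorted(node_attrs, key=_node_key):
        g.add_node(key, **node_attrs[key])
    for a, b, d in _msn_edges(list(node_attrs), weights, epsilon):
        positions = tuple(sorted({_token_position(t) for t in a ^ b}))
        g.add_edge(a, b, weight=d, positions=positions)
    return HaploNetwork(g, window)


def minimum_spanning_network(
    records: Sequence[SampleRecord],
    weights: Mapping[int, float] | None = None,
    epsilon: int = 0,
) -> HaploNetwork:
    """Network containing every edge present in at least one MST (relaxed by
    ``epsilon``); duplicate motifs are collapsed with summed frequencies."""
    nodes, window = _collapse(records)
    return _build_network(nodes, window, weights, epsilon)


def _median(a: frozenset[str], b: frozenset[str], c: frozenset[str]) -> frozenset[str]:
    counts: dict[str, int] = {}
    for s in (a, b, c):
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    return frozenset(t for t, k in counts.items() if k >= 2)


def median_joining(
    records: Sequence[SampleRecord],
    params: MJParams | None = None,
) -> HaploNetwork:
    """Median-joining network over the given motifs.

    Iterates: build the epsilon-MSN over current nodes; for every connected
    triplet (a node and two of its neighbours, or a triangle) propose the
    per-site majority median; add new medians whose connection cost lies
    within epsilon of the minimum; repeat until stable.  Finally remove
    unsampled medians of degree <= 2 that lie on no shortest path between
    sampled nodes.
    """
    params = params or MJParams()
    nodes, window = _collapse(records)
    sampled = set(nodes)

    for _ in range(params.max_iterations):
        net = _build_network(nodes, window, params.weights, params.epsilon)
        g = net.graph
        candidates: dict[frozenset[str], float] = {}
        for u, v, w in itertools.combinations(g.nodes, 3):
            m = _median(u, v, w)
            if m in nodes:
                continue
            cost = (
                _token_distance(u, m, params.weights)
                + _token_distance(v, m, params.weights)
                + _token_distance(w, m, params.weights)
            )
            if m not in candidates or cost < candidates[m]:
                candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        added = False
        for m, cost in sorted(candidates.items(), key=lambda kv: (_node_key(kv[0]),)):
            if cost <= lam + params.epsilon:
                nodes[m] = {"labels": (), "frequency": 0, "is_median": True}
                added = True
        if not added:
            break
    else:
        raise ConvergenceError(
            f"median joining did not converge in {params.max_iterations} iterations",
            len(nodes),
        )

    # reduction: drop useless medians (degree <= 2, on no sampled-to-sampled
    # shortest path), rebuilding the MSN after each removal
    while True:
        net = _build_network(nodes, window, params.weights, params.epsilon)
        g = net.graph
        dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        removable = None
        for m in sorted(nodes, key=_node_key):
            if m in sampled or g.degree(m) > 2:
                continue
            useful = any(
                abs(dist[s][m] + dist[m][t] - dist[s][t]) < 1e-9
                for s, t in itertools.combinations(sorted(sampled, key=_node_key), 2)
            )
            if not useful:
                removable = m
                break
        if removable is None:
            break
        del nodes[removable]

    return _build_network(nodes, window, params.weights, params.epsilon)


# ---------------------------------------------------------------------------
# export / import


def export_network(net: HaploNetwork, prefix: str | Path, fmt: str = "tsv") -> list[Path]:
    """Write node and edge tables (or GML).  Node ids are deterministic."""
    prefix = Path(prefix)
    if fmt == "gml":
        path = prefix.with_suffix(".gml")
        g = nx.relabel_nodes(net.graph, {n: ";".join(sorted(n)) for n in net.graph})
        for _, data in g.nodes(data=True):
            data["labels"] = ";".join(data["labels"])
        for _, _, data in g.edges(data=True):
            data["positions"] = ";".join(map(str, data["positions"]))
        nx.write_gml(g, str(path))
        return [path]
    if fmt != "tsv":
        raise InputError(f"unknown export format {fmt!r}")

    node_path = prefix.parent / f"{prefix.name}.nodes.tsv"
    edge_path = prefix.parent / f"{prefix.name}.edges.tsv"
    ids = {n: f"N{i:03d}" for i, n in enumerate(net.nodes())}
    node_lines = ["id\tmotif\tlabels\tfrequency\tis_median\twindow_start\twindow_end"]
    for n in net.nodes():
        d = net.graph.nodes[n]
        node_lines.append(
            "\t".join(
                [
                    ids[n],
                    ";".join(sorted(n)),
                    ";".join(d["labels"]),
                    str(d["frequency"]),
                    "1" if d["is_median"] else "0",
                    str(net.window[0]),
                    str(net.window[1]),
                ]
            )
        )
    edge_lines = ["from\tto\tpositions\tweight"]
    for a, b in sorted(net.graph.edges, key=lambda e: (_node_key(e[0]), _node_key(e[1]))):
        d = net.graph.edges[a, b]
        x, y = sorted((ids[a], ids[b]))
        edge_lines.append(
            "\t".join([x, y, ";".join(map(str, d["positions"])), repr(d["weight"])])
        )
    node_path.write_text("\n".join(node_lines) + "\n", encoding="utf-8")
    edge_path.write_text("\n".join(edge_lines) + "\n", encoding="utf-8")
    return [node_path, edge_path]


def read_network(prefix: str | Path) -> HaploNetwork:
    prefix = Path(prefix)
    node_path = prefix.parent / f"{prefix.name}.nodes.tsv"
    edge_path = prefix.parent / f"{prefix.name}.edges.tsv"
    g = nx.Graph()
    by_id: dict[str, frozenset[str]] = {}
    window = (0, 0)
    lines = node_path.read_text(encoding="utf-8").splitlines()
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 7:
            raise ParseError("bad node row", lineno)
        nid, motif_s, labels_s, freq, is_median, ws, we = fields
        key = frozenset(t for t in motif_s.split(";") if t)
        by_id[nid] = key
        window = (int(ws), int(we))
        g.add_node(
            key,
            labels=tuple(l for l in labels_s.split(";") if l),
            frequency=int(freq),
            is_median=is_median == "1",
        )
    for lineno, raw in enumerate(edge_path.read_text(encoding="utf-8").splitlines()[1:], start=2):
        if not raw.strip():
            continue
        a, b, positions_s, weight = raw.split("\t")
        g.add_edge(
            by_id[a],
            by_id[b],
            weight=float(weight),
            positions=tuple(int(p) for p in positions_s.split(";") if p),
        )
    return HaploNetwork(g, window)
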