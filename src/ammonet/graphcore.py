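"""From-scratch graph algorithms for biomarker-network analysis.

This module implements the graph machinery of the pipeline on a minimal
undirected simple-graph type:

* Brandes-style unweighted edge betweenness,
* Girvan-Newman divisive community detection with max-modularity selection,
* Newman-Girvan modularity Q,
* Bron-Kerbosch maximal-clique enumeration with pivoting,
* maximal clique centrality (MCC) hub scores.

Everything is deterministic: node iteration is always in sorted order,
edges are canonicalised as ``(min, max)`` tuples, and the Girvan-Newman
edge-removal tie-break is lexicographic.  Correlation networks are treated
as unweighted here; edge weights (Spearman rho) live as attributes on the
:class:`~ammonet.netbuild.OmicsNetwork` wrapper and do not influence path
counting or clique enumeration.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from math import factorial
from typing import Dict, Hashable, Iterable, List, Sequence, Tuple

Node = Hashable
Edge = Tuple[Node, Node]

__all__ = [
    "Graph",
    "CommunityPartition",
    "edge_betweenness",
    "modularity",
    "girvan_newman",
    "maximal_cliques",
    "mcc_scores",
]


def _canon(u: Node, v: Node) -> Edge:
    return (u, v) if u <= v else (v, u)


class Graph:
    """Undirected simple graph: no self-loops, no parallel edges."""

    def __init__(self, nodes: Iterable[Node] = (), edges: Iterable[Edge] = ()):
        self._adj: Dict[Node, set] = {}
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    def add_node(self, n: Node) -> None:
        self._adj.setdefault(n, set())

    def add_edge(self, u: Node, v: Node) -> None:
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r}")
        self.add_node(u)
        self.add_node(v)
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u: Node, v: Node) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def has_edge(self, u: Node, v: Node) -> bool:
        return v in self._adj.get(u, ())

    def neighbors(self, n: Node) -> set:
        return self._adj[n]

    def degree(self, n: Node) -> int:
        return len(self._adj[n])

    @property
    def nodes(self) -> List[Node]:
        return sorted(self._adj)

    @property
    def edges(self) -> List[Edge]:
        out = []
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if u <= v:
                    out.append((u, v))
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._adj.values()) // 2

    def copy(self) -> "Graph":
        g = Graph()
        g._adj = {n: set(s) for n, s in self._adj.items()}
        return g

    def subgraph(self, nodes: Iterable[Node]) -> "Graph":
        keep = set(nodes)
        g = Graph()
        for n in keep:
            g._adj[n] = self._adj[n] & keep
        return g

    def connected_components(self) -> List[frozenset]:
        """Components as frozensets, sorted by (size desc, min node) for determinism."""
        seen: set = set()
        comps = []
        for start in self.nodes:
            if start in seen:
                continue
            comp = {start}
            queue = deque([start])
            while queue:
                u = queue.popleft()
                for v in self._adj[u]:
                    if v not in comp:
                        comp.add(v)
                        queue.append(v)
            seen |= comp
            comps.append(frozenset(comp))
        return sorted(comps, key=lambda c: (-len(c), min(c)))

    def __eq__(self, other) -> bool:
        return isinstance(other, Graph) and self._adj == other._adj

    def __repr__(self) -> str:
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class CommunityPartition:
    """Disjoint node communities covering a graph plus the modularity Q.

    ``communities`` is sorted by (size desc, min member) and each community is a
    frozenset, so equal partitions compare equal.
    """

    communities: Tuple[frozenset, ...]
    modularity_q: float

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def labels(self) -> Dict[Node, int]:
        """node -> community index (by the canonical community ordering)."""
        return {n: i for i, c in enumerate(self.communities) for n in c}


def _sorted_communities(parts: Iterable[Iterable[Node]]) -> Tuple[frozenset, ...]:
    return tuple(sorted((frozenset(p) for p in parts), key=lambda c: (-len(c), min(c))))


def edge_betweenness(graph: Graph, nodes: Sequence[Node] | None = None) -> Dict[Edge, float]:
    """Unweighted edge betweenness: shortest-path pair counts through each edge.

    For every unordered node pair the unit of flow is split fractionally across
    the equal-length shortest paths joining the pair (Brandes accumulation over
    BFS DAGs).  ``nodes`` optionally restricts sources/targets to one component,
    which Girvan-Newman uses to rescore only the component it just cut.
    """
    if nodes is None:
        nodes = graph.nodes
    scores: Dict[Edge, float] = {}
    for u in nodes:
        for v in graph.neighbors(u):
            if u <= v:
                scores[(u, v)] = 0.0
    adj = graph._adj
    for s in nodes:
        # BFS from s: sigma = #shortest paths, preds on shortest-path DAG
        sigma = {s: 1.0}
        dist = {s: 0}
        preds: Dict[Node, List[Node]] = {s: []}
        order: List[Node] = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            order.append(u)
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0.0
                    preds[v] = []
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        # accumulate dependency of s on each edge
        delta = {u: 0.0 for u in order}
        for w in reversed(order):
            for v in preds[w]:
                c = sigma[v] / sigma[w] * (1.0 + delta[w])
                scores[_canon(v, w)] += c
                delta[v] += c
    # each unordered pair was counted from both endpoints
    return {e: x / 2.0 for e, x in scores.items()}


def modularity(graph: Graph, partition: Iterable[Iterable[Node]]) -> float:
    """Newman-Girvan modularity Q = sum_c [ l_c/m - (d_c/(2m))^2 ].

    ``l_c`` counts intra-community edges, ``d_c`` sums the (whole-graph) degrees
    of the community's members, ``m`` is the total edge count.  Raises on an
    edgeless graph, where Q is undefined.
    """
    m = graph.n_edges
    if m == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    comms = [set(c) for c in partition]
    covered = set()
    for c in comms:
        if covered & c:
            raise ValueError("partition communities overlap")
        covered |= c
    if covered != set(graph._adj):
        raise ValueError("partition does not cover the node set exactly")
    q = 0.0
    for c in comms:
        l_c = sum(1 for u in c for v in graph.neighbors(u) if v in c and u <= v)
        d_c = sum(graph.degree(u) for u in c)
        q += l_c / m - (d_c / (2.0 * m)) ** 2
    return q


def girvan_newman(graph: Graph) -> Tuple[CommunityPartition, List[CommunityPartition]]:
    """Divisive community detection by iterative max-betweenness edge removal.

    Removes one maximum-betweenness edge at a time (ties broken by the
    lexicographically smallest edge tuple); whenever a removal disconnects a
    component, the connected-component partition at that point is appended to
    the trace.  The trace starts with the input graph's own components (the
    coarsest candidate).  Returns ``(best, trace)`` where *best* maximises
    modularity Q over the trace, earliest (coarsest) partition winning ties.

    An edgeless graph yields the all-singletons partition with Q = 0.0 by
    convention (modularity proper is undefined without edges).
    """
    base = _sorted_communities(graph.connected_components())
    if graph.n_edges == 0:
        part = CommunityPartition(base, 0.0)
        return part, [part]

    trace = [CommunityPartition(base, modularity(graph, base))]
    work = graph.copy()
    # betweenness cache: rescore only the component containing the removed edge
    scores = edge_betweenness(work)
    n_comps = len(base)
    while work.n_edges:
        # deterministic tie-break: max score, then lexicographically smallest edge
        best_score = max(scores.values())
        e = min(ed for ed, sc in scores.items() if sc == best_score)
        work.remove_edge(*e)
        comps = work.connected_components()
        if len(comps) > n_comps:
            n_comps = len(comps)
            parts = _sorted_communities(comps)
            trace.append(CommunityPartition(parts, modularity(graph, parts)))
        # rescore within the component(s) that held e; other scores are unchanged
        affected = {n for c in comps if (e[0] in c or e[1] in c) for n in c}
        scores = {ed: sc for ed, sc in scores.items()
                  if ed != e and ed[0] not in affected and ed[1] not in affected}
        if affected:
            sub = work.subgraph(affected)
            scores.update(edge_betweenness(sub))
    best = max(trace, key=lambda p: p.modularity_q)
    # earliest partition achieving the max Q (coarsest, since trace is ordered)
    for p in trace:
        if p.modularity_q == best.modularity_q:
            best = p
            break
    return best, trace


def maximal_cliques(graph: Graph) -> List[Tuple[Node, ...]]:
    """All maximal cliques via Bron-Kerbosch with pivoting.

    Isolated nodes yield their singleton cliques.  Output is canonicalised:
    each clique is a sorted tuple and the clique list itself is sorted.
    """
    adj = graph._adj
    out: List[Tuple[Node, ...]] = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            out.append(tuple(sorted(r)))
            return
        pivot = max(p | x, key=lambda u: (len(adj[u] & p), u))
        for v in sorted(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(adj), set())
    return sorted(out)


def mcc_scores(graph: Graph) -> Dict[Node, int]:
    """Maximal clique centrality: MCC(v) = sum over maximal cliques C containing v
    of (|C| - 1)!.

    An isolated node sits in its singleton maximal clique and scores
    (1-1)! = 1, keeping every screened biomarker rankable.
    """
    scores = {n: 0 for n in graph._adj}
    for clique in maximal_cliques(graph):
        w = factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores
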