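"""Consistent relations, maximal consistent subgraphs and pathway scores.

A signed edge (i → j, r) is consistent when sign(t_i)·sign(t_j)·r = +1,
with NON-standardized t values: their signs carry the real direction of
change. The maximal consistent subgraphs are the weakly-connected
components of the consistent-edge subgraph — the unique inclusion-maximal
consistent subgraphs under the edgewise predicate. Each component scores
w(d)·Σz where d is its directed distance to the pathway's leaves, so
co-regulation near the pathway's terminal effectors weighs more.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from acst.pathway_io import PathwayGraph

logger = logging.getLogger(__name__)

INFINITE_DISTANCE = math.inf


@dataclass
class ConsistentSubgraph:
    """One maximal consistent subgraph: its nodes, (all-consistent) edges,
    directed leaf distance ``d`` and score ``w(d)·Σz``."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str, int]]
    d: float = INFINITE_DISTANCE
    score: float = 0.0

    def sum_z(self, z_by_gene: Mapping[str, float]) -> float:
        return float(sum(z_by_gene[n] for n in self.nodes))


@dataclass
class PathwayScore:
    pathway_id: str
    global_stat: float
    subgraphs: list[ConsistentSubgraph] = field(default_factory=list)


def sign(value: float) -> int:
    return int(value > 0) - int(value < 0)


def is_consistent(t_source: float, t_target: float, r: int) -> bool:
    """True iff sign(t_source)·sign(t_target)·r == +1.

    Zero statistics (possible via the variance floor) and neutral edges
    (r = 0) are never consistent.
    """
    return sign(t_source) * sign(t_target) * r == 1


def consistent_edges(g: PathwayGraph, t_by_gene: Mapping[str, float]) -> set[tuple[str, str, int]]:
    for node in g.nodes:
        if node not in t_by_gene:
            raise ValueError(f"node {node!r} has no t statistic")
    return {(s, t, r) for (s, t, r) in g.edges if is_consistent(t_by_gene[s], t_by_gene[t], r)}


def maximal_consistent_subgraphs(
    g: PathwayGraph, t_by_gene: Mapping[str, float]
) -> list[ConsistentSubgraph]:
    """Weakly-connected components of the consistent-edge subgraph.

    Returns one subgraph per component, containing every consistent edge
    among its nodes; distance and score are left unset. An empty list
    when no edge is consistent.
    """
    edges = consistent_edges(g, t_by_gene)
    if not edges:
        return []
    # union-find over edge endpoints
    parent: dict[str, str] = {}

    def find(a: str) -> str:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    for s, t, _ in edges:
        parent.setdefault(s, s)
        parent.setdefault(t, t)
        ra, rb = find(s), find(t)
        if ra != rb:
            parent[rb] = ra

    by_root: dict[str, tuple[set[str], set[tuple[str, str, int]]]] = {}
    for s, t, r in edges:
        root = find(s)
        nodes, comp_edges = by_root.setdefault(root, (set(), set()))
        nodes.update((s, t))
        comp_edges.add((s, t, r))
    components = [
        ConsistentSubgraph(nodes=frozenset(nodes), edges=frozenset(comp_edges))
        for nodes, comp_edges in by_root.values()
    ]
    components.sort(key=lambda c: min(c.nodes))
    return components


def leaves(g: PathwayGraph) -> set[str]:
    """Nodes with no outgoing edge and at least one incoming edge.

    Every edge counts, including neutral (r = 0) ones; isolated nodes are
    not leaves.
    """
    has_out = {s for s, _, _ in g.edges}
    has_in = {t for _, t, _ in g.edges}
    return has_in - has_out


def directed_distance(g: PathwayGraph, from_nodes: set[str], to_nodes: set[str]) -> float:
    """Minimum node count of a directed path from ``from_nodes`` into
    ``to_nodes``; 1 when the sets overlap, inf when unreachable.

    All edges of ``g`` are traversable regardless of sign.
    """
    if not from_nodes:
        raise ValueError("from_nodes is empty")
    if from_nodes & to_nodes:
        return 1
    if not to_nodes:
        return INFINITE_DISTANCE
    successors: dict[str, set[str]] = {}
    for s, t, _ in g.edges:
        successors.setdefault(s, set()).add(t)
    # BFS layer k holds nodes reachable by a path of k+1 nodes
    seen = set(from_nodes)
    frontier = set(from_nodes)
    depth = 1
    while frontier:
        depth += 1
        nxt: set[str] = set()
        for node in frontier:
            nxt |= successors.get(node, set())
        nxt -= seen
        if nxt & to_nodes:
            return depth
        seen |= nxt
        frontier = nxt
    return INFINITE_DISTANCE


WeightFn = Callable[[float], float]


def reciprocal_weight(d: float) -> float:
    """Default position weight w(d) = 1/d, w(inf) = 0."""
    return 0.0 if math.isinf(d) else 1.0 / d


def exponential_weight(lam: float) -> WeightFn:
    """Alternate decay w(d) = exp(-lam·(d-1)), w(inf) = 0."""

    def w(d: float) -> float:
        return 0.0 if math.isinf(d) else math.exp(-lam * (d - 1.0))

    return w


def parse_weight(spec: str) -> WeightFn:
    """Parse a weight spec: ``reciprocal`` or ``exponential:<lam>``."""
    if spec == "reciprocal":
        return reciprocal_weight
    if spec.startswith("exponential:"):
        return exponential_weight(float(spec.split(":", 1)[1]))
    raise ValueError(f"unknown weight spec {spec!r}")


def subgraph_score(
    c: ConsistentSubgraph,
    z_by_gene: Mapping[str, float],
    d: float,
    weight: WeightFn = reciprocal_weight,
) -> float:
    """γ(C) = w(d) · Σ_{g ∈ C} z_g."""
    for node in c.nodes:
        if node not in z_by_gene:
            raise ValueError(f"node {node!r} has no standardized statistic")
    return weight(d) * c.sum_z(z_by_gene)


def global_statistic(
    g: PathwayGraph,
    t_by_gene: Mapping[str, float],
    z_by_gene: Mapping[str, float],
    weight: WeightFn = reciprocal_weight,
) -> PathwayScore:
    """Sum of scores of all maximal consistent subgraphs of ``g``.

    Leafless graphs (pure cycles) fall back to weight 1 for every
    subgraph, with a warning, instead of silently scoring 0.
    """
    components = maximal_consistent_subgraphs(g, t_by_gene)
    leaf_set = leaves(g)
    leafless = not leaf_set
    if leafless and components:
        logger.warning("pathway %s has no leaves; using weight 1 for all subgraphs", g.pathway_id)
    scored: list[ConsistentSubgraph] = []
    for comp in components:
        if leafless:
            d = INFINITE_DISTANCE
            score = comp.sum_z(z_by_gene)  # fallback w = 1
        else:
            d = directed_distance(g, set(comp.nodes), leaf_set)
            score = subgraph_score(comp, z_by_gene, d, weight)
        scored.append(ConsistentSubgraph(nodes=comp.nodes, edges=comp.edges, d=d, score=score))
    scored.sort(key=lambda c: (-c.score, min(c.nodes)))
    return PathwayScore(
        pathway_id=g.pathway_id,
        global_stat=float(sum(c.score for c in scored)),
        subgraphs=scored,
    )


class PathwayScorer:
    """Array-compiled pathway for fast repeated scoring.

    Pre-resolves node → universe-row indices and per-node directed leaf
    distances (topology only, so they are permutation-invariant); scoring
    a new t/z vector is then a sign test on the signed edges plus a
    union-find over at most ``n_nodes`` elements.

    Produces global statistics identical to :func:`global_statistic`
    (property-tested); used by the permutation null.
    """

    def __init__(self, g: PathwayGraph, universe_index: Mapping[str, int], weight: WeightFn = reciprocal_weight):
        self.pathway_id = g.pathway_id
        self.node_names = g.sorted_nodes()
        local = {n: i for i, n in enumerate(self.node_names)}
        self.universe_rows = np.array([universe_index[n] for n in self.node_names], dtype=np.intp)
        signed = [(s, t, r) for (s, t, r) in g.sorted_edges() if r != 0]
        self.esrc = np.array([local[s] for s, _, _ in signed], dtype=np.intp)
        self.etgt = np.array([local[t] for _, t, _ in signed], dtype=np.intp)
        self.esign = np.array([r for _, _, r in signed], dtype=np.int8)
        leaf_set = leaves(g)
        self.leafless = not leaf_set
        if self.leafless:
            self.node_weight = [1.0] * len(self.node_names)
        else:
            dist = _node_leaf_distances(g, leaf_set)
            self.node_weight = [weight(dist[n]) for n in self.node_names]
        # weight of a component = weight of the best-placed member node
        # (min distance == max weight for any monotone decreasing weight)
        self.n_nodes = len(self.node_names)

    def score(self, t_universe: np.ndarray, z_universe: np.ndarray) -> float:
        if self.esrc.size == 0:
            return 0.0
        t_local = t_universe[self.universe_rows]
        signs = np.sign(t_local).astype(np.int8)
        ok = signs[self.esrc] * signs[self.etgt] * self.esign == 1
        if not ok.any():
            return 0.0
        z_local = z_universe[self.universe_rows]
        parent = list(range(self.n_nodes))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        members: set[int] = set()
        for s, t in zip(self.esrc[ok].tolist(), self.etgt[ok].tolist()):
            members.add(s)
            members.add(t)
            ra, rb = find(s), find(t)
            if ra != rb:
                parent[rb] = ra

        zsum: dict[int, float] = {}
        wmax: dict[int, float] = {}
        for node in members:
            root = find(node)
            zsum[root] = zsum.get(root, 0.0) + float(z_local[node])
            w = self.node_weight[node]
            if w > wmax.get(root, -1.0):
                wmax[root] = w
        return float(sum(wmax[r] * zsum[r] for r in zsum))


def _node_leaf_distances(g: PathwayGraph, leaf_set: set[str]) -> dict[str, float]:
    """Directed distance (node count) from each node to the leaf set,
    via reverse BFS from the leaves."""
    predecessors: dict[str, set[str]] = {}
    for s, t, _ in g.edges:
        predecessors.setdefault(t, set()).add(s)
    dist = {n: INFINITE_DISTANCE for n in g.nodes}
    frontier = set(leaf_set)
    for n in frontier:
        dist[n] = 1
    depth = 1
    while frontier:
        depth += 1
        nxt: set[str] = set()
        for node in frontier:
            for pred in predecessors.get(node, ()):
                if math.isinf(dist[pred]):
                    dist[pred] = depth
                    nxt.add(pred)
        frontier = nxt
    return dist


def compile_scorers(
    catalog: Sequence[PathwayGraph],
    universe: Sequence[str],
    weight: WeightFn = reciprocal_weight,
) -> list[PathwayScorer]:
    index = {g: i for i, g in enumerate(universe)}
    return [PathwayScorer(g, index, weight) for g in catalog]
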