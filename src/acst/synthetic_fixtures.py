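"""Synthetic pathway catalogs and expression data with planted cascades.

Everything here is seeded and bit-reproducible, so the whole pipeline is
testable without any external pathway database or expression repository.
Also hosts the brute-force subgraph oracle used to validate the
consistency engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from acst.consistency_engine import ConsistentSubgraph, consistent_edges
from acst.expression_io import ExpressionDataset
from acst.pathway_io import PathwayGraph


@dataclass
class PlantSpec:
    """A consistent cascade planted into the test group.

    ``cascade_nodes`` form a directed chain in the pathway with signs
    ``edge_signs``; gene k of the chain is shifted by
    effect·noise_sd·σ_k in the test group, σ_k being the cumulative
    product of the edge signs (σ_1 = +1). With effect > 0 the chain is
    therefore consistent by construction.
    """

    pathway_id: str
    cascade_nodes: list[str]
    edge_signs: list[int] = field(default_factory=list)
    effect: float = 2.0
    at_leaf: bool = True

    def __post_init__(self) -> None:
        if len(self.edge_signs) != max(len(self.cascade_nodes) - 1, 0):
            raise ValueError("edge_signs must have one sign per chain edge")
        if any(s not in (-1, 1) for s in self.edge_signs):
            raise ValueError("edge signs must be ±1")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")

    def shift_signs(self) -> list[int]:
        """σ_k per cascade gene: cumulative product of edge signs."""
        sigma = [1]
        for s in self.edge_signs:
            sigma.append(sigma[-1] * s)
        return sigma


def random_pathway(
    n_nodes: int,
    n_edges: int,
    activation_fraction: float = 0.7,
    neutral_fraction: float = 0.1,
    seed: int = 0,
    pathway_id: str = "synthetic",
    node_prefix: str | None = None,
) -> PathwayGraph:
    """Simple directed random graph with i.i.d. edge signs.

    Signs are +1 / 0 / -1 with probabilities activation_fraction,
    neutral_fraction and the remainder. Node ids are prefixed with the
    pathway id by default so catalogs have disjoint gene sets.
    """
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    if not (0 <= activation_fraction <= 1 and 0 <= neutral_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if activation_fraction + neutral_fraction > 1:
        raise ValueError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    prefix = f"{pathway_id}_" if node_prefix is None else node_prefix
    width = len(str(max(n_nodes - 1, 1)))
    names = [f"{prefix}g{i:0{width}d}" for i in range(n_nodes)]
    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    signs = rng.choice(
        [1, 0, -1],
        size=n_edges,
        p=[activation_fraction, neutral_fraction, 1 - activation_fraction - neutral_fraction],
    )
    edges = {(names[pairs[k][0]], names[pairs[k][1]], int(s)) for k, s in zip(chosen, signs)}
    return PathwayGraph(
        pathway_id=pathway_id, name=pathway_id, nodes=set(names), edges=edges, provenance="synthetic"
    )


def cascade_pathway(
    n_nodes: int,
    chain_len: int,
    n_extra_edges: int = 0,
    activation_fraction: float = 0.7,
    seed: int = 0,
    pathway_id: str = "planted",
) -> tuple[PathwayGraph, PlantSpec]:
    """Pathway embedding a directed chain whose terminus is a leaf.

    The last ``chain_len`` of the ``n_nodes`` nodes form the chain; extra
    random edges are added among the remaining nodes and into (never out
    of) the chain's terminus, so the terminus stays a leaf and the chain
    sits at directed distance 1 from the leaf set.
    """
    if chain_len < 2 or chain_len > n_nodes:
        raise ValueError("need 2 <= chain_len <= n_nodes")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_nodes - 1, 1)))
    names = [f"{pathway_id}_g{i:0{width}d}" for i in range(n_nodes)]
    chain = names[n_nodes - chain_len :]
    edge_signs = [int(s) for s in rng.choice([1, -1], size=chain_len - 1, p=[activation_fraction, 1 - activation_fraction])]
    edges = {(chain[k], chain[k + 1], edge_signs[k]) for k in range(chain_len - 1)}
    terminus = chain[-1]
    candidates = [
        (a, b)
        for a in names
        for b in names
        if a != b and a != terminus and (a, b) not in {(s, t) for s, t, _ in edges}
    ]
    if n_extra_edges > len(candidates):
        raise ValueError("too many extra edges requested")
    for k in rng.choice(len(candidates), size=n_extra_edges, replace=False):
        a, b = candidates[k]
        edges.add((a, b, int(rng.choice([1, -1, 0], p=[0.6, 0.2, 0.2]))))
    graph = PathwayGraph(
        pathway_id=pathway_id, name=pathway_id, nodes=set(names), edges=edges, provenance="synthetic"
    )
    plant = PlantSpec(pathway_id=pathway_id, cascade_nodes=list(chain), edge_signs=edge_signs, at_leaf=True)
    return graph, plant


def simulate_expression(
    catalog: Sequence[PathwayGraph],
    plants: Sequence[PlantSpec] = (),
    n_test: int = 10,
    n_control: int = 10,
    noise_sd: float = 1.0,
    seed: int = 0,
    effect: float | None = None,
) -> ExpressionDataset:
    """Two-group expression over all catalog genes with optional cascades.

    Baseline values are i.i.d. Normal(0, noise_sd). Each planted cascade
    adds effect·noise_sd·σ_k to gene k of the chain in the test group.
    ``effect`` overrides every plant's own effect when given.
    """
    if n_test < 2 or n_control < 2:
        raise ValueError("each group needs >= 2 subjects")
    genes = sorted(set().union(*[g.nodes for g in catalog])) if catalog else []
    if not genes:
        raise ValueError("catalog has no genes")
    gene_row = {g: i for i, g in enumerate(genes)}
    for plant in plants:
        for node in plant.cascade_nodes:
            if node not in gene_row:
                raise ValueError(f"planted gene {node!r} not in the catalog")
    rng = np.random.default_rng(seed)
    n = n_test + n_control
    values = rng.normal(0.0, noise_sd, size=(len(genes), n))
    for plant in plants:
        eff = plant.effect if effect is None else effect
        for node, sigma in zip(plant.cascade_nodes, plant.shift_signs()):
            values[gene_row[node], :n_test] += eff * noise_sd * sigma
    subjects = [f"t{i:02d}" for i in range(n_test)] + [f"c{i:02d}" for i in range(n_control)]
    labels = np.array(["test"] * n_test + ["control"] * n_control, dtype=object)
    return ExpressionDataset(genes=genes, subjects=subjects, values=values, labels=labels, test_label="test")


def brute_force_maximal_subgraphs(
    g: PathwayGraph, t_by_gene: Mapping[str, float]
) -> list[ConsistentSubgraph]:
    """Oracle: enumerate every nonempty subset of consistent edges, keep
    the weakly-connected ones, and return the setwise-maximal survivors.

    Exponential in the consistent edge count; guarded to graphs of at
    most 10 nodes.
    """
    if len(g.nodes) > 10:
        raise ValueError("brute force oracle limited to graphs of <= 10 nodes")
    cons = sorted(consistent_edges(g, t_by_gene))
    maximal: list[frozenset] = []
    for size in range(1, len(cons) + 1):
        for subset in itertools.combinations(cons, size):
            if not _weakly_connected(subset):
                continue
            # a connected strict superset always admits a one-edge adjacent
            # extension, so maximal ⟺ no outside consistent edge touches us
            nodes = {n for s, t, _ in subset for n in (s, t)}
            chosen = set(subset)
            if any(e not in chosen and (e[0] in nodes or e[1] in nodes) for e in cons):
                continue
            maximal.append(frozenset(subset))
    out = []
    for edge_set in maximal:
        nodes = frozenset(itertools.chain.from_iterable((s, t) for s, t, _ in edge_set))
        out.append(ConsistentSubgraph(nodes=nodes, edges=edge_set))
    out.sort(key=lambda c: min(c.nodes))
    return out


def _weakly_connected(edges) -> bool:
    adjacency: dict[str, set[str]] = {}
    for s, t, _ in edges:
        adjacency.setdefault(s, set()).add(t)
        adjacency.setdefault(t, set()).add(s)
    start = next(iter(adjacency))
    seen = {start}
    stack = [start]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(adjacency)
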