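"""Pathway input: KGML documents and a plain signed edge-list dialect.

Only gene nodes and gene-expression relations (KGML ``GErel``) survive
parsing: the downstream consistency test is defined on transcription
factor → target edges whose effect is visible in mRNA levels. Protein-level
relation classes (PPrel, ECrel, maplink) are discarded.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable

logger = logging.getLogger(__name__)

#: edge sign: +1 activation, -1 repression, 0 neutral/unknown
VALID_SIGNS = (-1, 0, 1)

_SIGN_TOKENS = {
    "+1": 1,
    "1": 1,
    "activation": 1,
    "-1": -1,
    "repression": -1,
    "0": 0,
    "neutral": 0,
}

_TOKEN_OF_SIGN = {1: "activation", -1: "repression", 0: "neutral"}


class PathwayParseError(ValueError):
    """Raised on malformed pathway input (bad XML, bad edge-list line)."""


@dataclass
class PathwayGraph:
    """Directed graph of gene nodes with signed regulation edges.

    Edges are ``(source, target, r)`` triples with ``r`` in {-1, 0, +1}.
    Parallel edges that differ in ``r`` are allowed; self-loops are not.
    """

    pathway_id: str
    name: str = ""
    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str, int]] = field(default_factory=set)
    provenance: str = "edgelist"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for src, tgt, r in self.edges:
            if src == tgt:
                raise ValueError(f"self-loop edge on node {src!r}")
            if r not in VALID_SIGNS:
                raise ValueError(f"edge sign {r!r} not in {VALID_SIGNS}")
            if src not in self.nodes or tgt not in self.nodes:
                raise ValueError(f"edge ({src!r}, {tgt!r}) has endpoint outside nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def sorted_edges(self) -> list[tuple[str, str, int]]:
        return sorted(self.edges)


def parse_kgml(document: str, default_id: str = "") -> PathwayGraph:
    """Parse a KGML document into a :class:`PathwayGraph`.

    Keeps only ``entry`` elements of type ``gene`` (multi-gene entries are
    expanded to one node per gene id, with incident relations replicated to
    every member) and only ``relation`` elements of type ``GErel``. The
    relation subtype maps to the edge sign: ``expression`` → +1,
    ``repression`` → -1, anything else or missing → 0. Self-loops arising
    from expansion are dropped and duplicate triples are deduplicated.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line, col = exc.position
        raise PathwayParseError(
            f"malformed KGML: {exc.msg if hasattr(exc, 'msg') else exc} "
            f"at line {line}, column {col} (byte offset ~{_byte_offset(document, line, col)})"
        ) from exc

    pathway_id = root.get("name", "") or default_id
    if pathway_id.startswith("path:"):
        pathway_id = pathway_id[len("path:") :]
    name = root.get("title", "")

    genes_by_entry: dict[str, list[str]] = {}
    nodes: set[str] = set()
    for entry in root.iter("entry"):
        if entry.get("type") != "gene":
            continue
        members = entry.get("name", "").split()
        if not members:
            continue
        genes_by_entry[entry.get("id", "")] = members
        nodes.update(members)

    edges: set[tuple[str, str, int]] = set()
    for relation in root.iter("relation"):
        if relation.get("type") != "GErel":
            continue
        sources = genes_by_entry.get(relation.get("entry1", ""))
        targets = genes_by_entry.get(relation.get("entry2", ""))
        if not sources or not targets:
            continue
        subtypes = {st.get("name") for st in relation.iter("subtype")}
        if "expression" in subtypes:
            r = 1
        elif "repression" in subtypes:
            r = -1
        else:
            r = 0
        for src in sources:
            for tgt in targets:
                if src != tgt:
                    edges.add((src, tgt, r))

    if not nodes:
        logger.warning("KGML pathway %r contains no gene entries", pathway_id or default_id)
    return PathwayGraph(
        pathway_id=pathway_id or default_id,
        name=name,
        nodes=nodes,
        edges=edges,
        provenance="kgml",
    )


def _byte_offset(document: str, line: int, col: int) -> int:
    lines = document.encode("utf-8", errors="replace").split(b"\n")
    return sum(len(l) + 1 for l in lines[: line - 1]) + col


def parse_edgelist(text: str, pathway_id: str = "", name: str = "") -> PathwayGraph:
    """Parse the TSV edge-list dialect: ``source<TAB>target<TAB>sign``.

    Sign tokens: ``+1``/``1``/``activation``, ``-1``/``repression``,
    ``0``/``neutral``. ``#`` lines are comments; ``# pathway_id:`` and
    ``# name:`` comments carry metadata. An optional header line
    ``source<TAB>target<TAB>sign`` is skipped. Nodes are implicit from
    edge endpoints; an optional ``node`` line (``source`` only) declares
    an isolated node.
    """
    nodes: set[str] = set()
    edges: set[tuple[str, str, int]] = set()
    n_lines = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            for key in ("pathway_id", "name"):
                if body.startswith(key + ":"):
                    value = body[len(key) + 1 :].strip()
                    if key == "pathway_id" and not pathway_id:
                        pathway_id = value
                    elif key == "name" and not name:
                        name = value
            continue
        fields = line.split("\t")
        if fields == ["source", "target", "sign"]:
            continue
        n_lines += 1
        if len(fields) == 1:
            nodes.add(fields[0])
            continue
        if len(fields) != 3:
            raise PathwayParseError(f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}")
        src, tgt, token = (f.strip() for f in fields)
        if token not in _SIGN_TOKENS:
            raise PathwayParseError(f"line {lineno}: unknown sign token {token!r}")
        if src == tgt:
            raise PathwayParseError(f"line {lineno}: self-loop on node {src!r}")
        triple = (src, tgt, _SIGN_TOKENS[token])
        if triple in edges:
            raise PathwayParseError(f"line {lineno}: duplicate edge {triple!r}")
        edges.add(triple)
        nodes.update((src, tgt))
    if n_lines == 0:
        logger.warning("edge list %r is empty", pathway_id)
    return PathwayGraph(pathway_id=pathway_id, name=name, nodes=nodes, edges=edges, provenance="edgelist")


def write_edgelist(g: PathwayGraph) -> str:
    """Serialize a graph in the edge-list dialect; inverse of :func:`parse_edgelist`."""
    lines = [f"# pathway_id: {g.pathway_id}"]
    if g.name:
        lines.append(f"# name: {g.name}")
    lines.append("source\ttarget\tsign")
    covered: set[str] = set()
    for src, tgt, r in g.sorted_edges():
        lines.append(f"{src}\t{tgt}\t{_TOKEN_OF_SIGN[r]}")
        covered.update((src, tgt))
    for node in sorted(g.nodes - covered):
        lines.append(node)
    return "\n".join(lines) + "\n"


def restrict_to_measured(g: PathwayGraph, universe: Iterable[str]) -> PathwayGraph:
    """Induced subgraph on ``nodes ∩ universe``.

    Edges touching a removed node are dropped; paths are NOT contracted
    through removed nodes. Idempotent.
    """
    keep = g.nodes & set(universe)
    dropped = len(g.nodes) - len(keep)
    if dropped:
        logger.info("pathway %s: dropped %d unmeasured node(s)", g.pathway_id, dropped)
    if not keep:
        logger.warning("pathway %s: no node is measured", g.pathway_id)
    edges = {(s, t, r) for (s, t, r) in g.edges if s in keep and t in keep}
    return PathwayGraph(
        pathway_id=g.pathway_id,
        name=g.name,
        nodes=keep,
        edges=edges,
        provenance=g.provenance,
    )
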