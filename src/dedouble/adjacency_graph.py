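"""The dedoubled adjacency graph A(G) of a totally duplicated genome.

Vertices are the adjacencies of G.  Every couple ``x`` contributes
exactly two edges pairing paralog extremities across the copies:

* ``E_head(x)`` joins the adjacency housing head(plain copy) to the
  adjacency housing tail(bar copy);
* ``E_tail(x)`` joins the adjacency housing tail(plain copy) to the
  adjacency housing head(bar copy).

Under this pairing a couple yields a self-loop exactly when it is in a
sorted (dedoubled) form ``(x x')`` or ``(x' x)``.  Every vertex has
degree one (telomeric) or two, so the connected components — the
*elements* of the graph — are paths and cycles: a genome with one linear
chromosome yields exactly one path, and possibly several cycles.

An element is *duplicated* if it contains both edges of some couple;
two elements *intersect* if they share a couple, otherwise they are
*independent*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import NotTotallyDuplicated, NotUnichromosomal
from .genome import (
    BAR,
    HEAD,
    PLAIN,
    TAIL,
    Adjacency,
    Extremity,
    Genome,
    classify,
    extremity_map,
)

E_HEAD = "head"
E_TAIL = "tail"


@dataclass(frozen=True)
class Edge:
    """One of the two paralog-pairing edges of a couple."""

    family: int
    which: str  # E_HEAD or E_TAIL
    u: Adjacency
    v: Adjacency

    def endpoints(self) -> tuple[Adjacency, Adjacency]:
        return (self.u, self.v)

    def extremity_pair(self) -> tuple[Extremity, Extremity]:
        if self.which == E_HEAD:
            return ((self.family, PLAIN, HEAD), (self.family, BAR, TAIL))
        return ((self.family, PLAIN, TAIL), (self.family, BAR, HEAD))

    @property
    def is_self_loop(self) -> bool:
        return self.u == self.v

    def sort_key(self) -> tuple:
        return (self.family, 0 if self.which == E_HEAD else 1)


@dataclass
class GraphElement:
    """A connected component of A(G): a path or a cycle."""

    kind: str  # "path" | "cycle"
    vertices: list[Adjacency]
    edges: list[Edge]

    @property
    def couples(self) -> list[int]:
        """Couples contained, with multiplicity."""
        return [e.family for e in self.edges]

    @property
    def couple_set(self) -> frozenset[int]:
        return frozenset(e.family for e in self.edges)

    @property
    def duplicated(self) -> bool:
        c = self.couples
        return len(c) != len(set(c))

    @property
    def size(self) -> int:
        return len(self.edges)

    def sort_key(self) -> tuple:
        return (0 if self.kind == "path" else 1,
                tuple(sorted(e.sort_key() for e in self.edges)),
                self.vertices[0].sort_key() if self.vertices else ())


@dataclass
class AdjacencyGraph:
    genome: Genome
    vertices: list[Adjacency]
    edges: list[Edge]
    elements: list[GraphElement] = field(default_factory=list)

    @property
    def couples(self) -> list[int]:
        return sorted({e.family for e in self.edges})

    @property
    def n(self) -> int:
        return len(self.couples)

    @property
    def paths(self) -> list[GraphElement]:
        return [el for el in self.elements if el.kind == "path"]

    @property
    def cycles(self) -> list[GraphElement]:
        return [el for el in self.elements if el.kind == "cycle"]

    def edge(self, family: int, which: str) -> Edge:
        for e in self.edges:
            if e.family == family and e.which == which:
                return e
        raise KeyError((family, which))

    def couple_oriented(self, family: int) -> bool:
        """A couple is oriented when its two copies carry opposite signs
        as written in the genome."""
        signs = [m.sign for m in self.genome.markers() if m.family == family]
        if len(signs) != 2:
            raise KeyError(family)
        return signs[0] != signs[1]


def build_adjacency_graph(g: Genome) -> AdjacencyGraph:
    """Construct A(G) and decompose it into path/cycle elements.

    Raises :class:`NotTotallyDuplicated` unless every family of ``g``
    occurs twice.
    """
    kind, _ = classify(g)
    if kind != "totally_duplicated":
        raise NotTotallyDuplicated(f"genome is {kind}")
    ext = extremity_map(g)
    families = sorted(g.duplicated_families())

    edges: list[Edge] = []
    for f in families:
        edges.append(Edge(f, E_HEAD, ext[(f, PLAIN, HEAD)], ext[(f, BAR, TAIL)]))
        edges.append(Edge(f, E_TAIL, ext[(f, PLAIN, TAIL)], ext[(f, BAR, HEAD)]))

    vertices = sorted({a for e in edges for a in e.endpoints()}, key=Adjacency.sort_key)
    graph = AdjacencyGraph(g, vertices, edges)
    graph.elements = _decompose(graph, ext)
    return graph


def _decompose(graph: AdjacencyGraph, ext: dict[Extremity, Adjacency]) -> list[GraphElement]:
    # each marker extremity is an endpoint of exactly one edge; walk
    # elements by entering a vertex through one extremity slot and
    # leaving through the other.
    edge_of_slot: dict[Extremity, Edge] = {}
    for e in graph.edges:
        for slot in e.extremity_pair():
            edge_of_slot[slot] = e

    def partner_slot(edge: Edge, slot: Extremity) -> Extremity:
        a, b = edge.extremity_pair()
        return b if slot == a else a

    visited_edges: set[tuple[int, str]] = set()
    elements: list[GraphElement] = []

    def walk(start_slot: Extremity) -> tuple[list[Adjacency], list[Edge], bool]:
        """Follow the element starting by leaving through ``start_slot``.
        Returns (vertices, edges, closed)."""
        verts = [ext[start_slot]]
        eds: list[Edge] = []
        slot = start_slot
        while True:
            edge = edge_of_slot[slot]
            if (edge.family, edge.which) in visited_edges:
                return verts, eds, True
            visited_edges.add((edge.family, edge.which))
            eds.append(edge)
            other = partner_slot(edge, slot)
            vertex = ext[other]
            exits = [s for s in vertex.extremities() if s != other]
            if not exits:  # telomeric vertex: end of a path
                verts.append(vertex)
                return verts, eds, False
            verts.append(vertex)
            slot = exits[0]

    # paths first: start from telomeric (degree-1) vertices
    for v in graph.vertices:
        exts = v.extremities()
        if len(exts) != 1:
            continue
        slot = exts[0]
        edge = edge_of_slot[slot]
        if (edge.family, edge.which) in visited_edges:
            continue
        verts, eds, _closed = walk(slot)
        elements.append(GraphElement("path", verts, eds))

    # remaining edges belong to cycles
    for e in sorted(graph.edges, key=Edge.sort_key):
        if (e.family, e.which) in visited_edges:
            continue
        a, _ = e.extremity_pair()
        verts, eds, closed = walk(a)
        assert closed, "non-telomeric walk must close into a cycle"
        elements.append(GraphElement("cycle", verts[:-1] if verts[-1] == verts[0] and len(verts) > 1 else verts, eds))

    elements.sort(key=GraphElement.sort_key)
    return elements


def element_relations(graph: AdjacencyGraph) -> dict[tuple[int, int], str]:
    """Pairwise classification of elements: ``intersect`` when two
    elements share a couple, ``independent`` otherwise.  Keys are index
    pairs (i < j) into ``graph.elements``."""
    out: dict[tuple[int, int], str] = {}
    els = graph.elements
    for i in range(len(els)):
        for j in range(i + 1, len(els)):
            shared = els[i].couple_set & els[j].couple_set
            out[(i, j)] = "intersect" if shared else "independent"
    return out


def path_validity(graph: AdjacencyGraph) -> tuple[bool, frozenset[int]]:
    """Whether the unique path of a unichromosomal linear genome's A(G)
    contains every couple; returns the missing couples otherwise."""
    paths = graph.paths
    if len(paths) != 1:
        raise NotUnichromosomal(f"expected exactly one path, found {len(paths)}")
    missing = frozenset(graph.couples) - paths[0].couple_set
    return (not missing, missing)


def edge_orientation(graph: AdjacencyGraph, family: int) -> bool:
    """Oriented flag of a couple's edges (copies written with opposite
    signs)."""
    if not graph.genome.unichromosomal_linear:
        raise NotUnichromosomal("edge orientation is defined on a single linear chromosome")
    return graph.couple_oriented(family)


def oriented_edge(graph: AdjacencyGraph, edge: Edge) -> bool:
    """An edge is oriented if the two copies of its couple have
    different signs (used by the extraction criterion of the reversal
    solver)."""
    return graph.couple_oriented(edge.family)


def to_dot(graph: AdjacencyGraph) -> str:
    """DOT export; elements are colored, edges labelled family:E_head/E_tail."""
    palette = ["black", "blue", "red", "darkgreen", "orange", "purple",
               "brown", "cadetblue", "magenta", "gray40"]
    lines = ["graph adjacency_graph {"]
    vid = {v: f"v{i}" for i, v in enumerate(graph.vertices)}
    for v, name in vid.items():
        lines.append(f'  {name} [label="{v}"];')
    for k, el in enumerate(graph.elements):
        color = palette[k % len(palette)]
        for e in el.edges:
            label = f"{e.family}:E_{e.which}"
            lines.append(f'  {vid[e.u]} -- {vid[e.v]} [label="{label}", color={color}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
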