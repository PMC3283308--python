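"""Reversal dedoubling of oriented unichromosomal linear genomes.

The solver works on the *dedoubled overlap graph*: one vertex per
couple, carrying the smallest position interval containing both copies;
an edge joins two couples whose intervals properly cross (they
intersect but neither contains the other).  A vertex is *oriented* when
its two copies carry opposite signs; it is *sorted* when the copies
already form a dedoubled adjacency (which forces equal signs and an
isolated length-one interval, so sorted vertices are excluded from the
component classification).  A genome is *oriented* when every component
containing an unsorted vertex contains at least one oriented vertex.

For an oriented vertex x there are two sorting reversals: ``rho``
reverses the markers strictly after the left copy up to and including
the right copy, ``rho_bar`` the mirror image; both leave the couple in
dedoubled form and act on the overlap graph by local complementation of
the closed neighbourhood, flipping its orientations.

The reversal dedoubling distance of an oriented genome is
``n - C + 2m`` (``n - C`` when the path of the adjacency graph is
already valid).  The sorter first merges every cycle outside the
selected independent set into the path with a merging reversal — which
never strands an unoriented component — then repeatedly applies a
maximum-score sorting reversal, verifying at each step that the exact
distance drops by one and falling back to an exhaustive search over
oriented vertices and variants if the preferred choice stalls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .adjacency_graph import GraphElement, build_adjacency_graph
from .cycle_selection import (
    DEFAULT_EXACT_LIMIT,
    build_conflict_graph,
    max_independent_cycles,
    merge_count,
)
from .dcj import DistanceReport, dcj_distance_linear
from .errors import (
    InternalError,
    NotUnichromosomal,
    UnorientedGenomeError,
    UnorientedVertex,
)
from .genome import TELOMERE, Adjacency, Genome, is_dedoubled
from .rearrange import RearrangementOp, Scenario, make_reversal, reverse_segment


@dataclass(frozen=True)
class OverlapVertex:
    """A couple of paralogs seen as an interval on the chromosome."""

    family: int
    left: int   # 1-based position of the leftmost copy
    right: int  # 1-based position of the rightmost copy
    left_sign: int
    right_sign: int

    @property
    def oriented(self) -> bool:
        return self.left_sign != self.right_sign

    @property
    def sorted(self) -> bool:
        # a dedoubled adjacency means adjacent positions with equal signs
        return self.right == self.left + 1 and self.left_sign == self.right_sign

    @property
    def interval(self) -> tuple[int, int]:
        return (self.left, self.right)


@dataclass
class OverlapGraph:
    vertices: dict[int, OverlapVertex]
    edges: set[frozenset[int]] = field(default_factory=set)

    def neighbors(self, family: int) -> set[int]:
        out = set()
        for e in self.edges:
            if family in e:
                (other,) = e - {family}
                out.add(other)
        return out

    def components(self) -> list[frozenset[int]]:
        seen: set[int] = set()
        comps: list[frozenset[int]] = []
        for f in sorted(self.vertices):
            if f in seen:
                continue
            comp = {f}
            stack = [f]
            while stack:
                x = stack.pop()
                for y in self.neighbors(x):
                    if y not in comp:
                        comp.add(y)
                        stack.append(y)
            seen |= comp
            comps.append(frozenset(comp))
        return comps


def _positions(g: Genome) -> list:
    if not g.unichromosomal_linear:
        raise NotUnichromosomal("overlap graph needs one linear chromosome")
    return list(g.chromosomes[0].markers)


def build_overlap_graph(g: Genome) -> OverlapGraph:
    """Dedoubled overlap graph of a totally duplicated single linear
    chromosome."""
    build_adjacency_graph(g)  # validates total duplication
    ms = _positions(g)
    occ: dict[int, list[tuple[int, int]]] = {}
    for pos, m in enumerate(ms, start=1):
        occ.setdefault(m.family, []).append((pos, m.sign))
    vertices = {}
    for f, pair in occ.items():
        (i, si), (j, sj) = pair
        vertices[f] = OverlapVertex(f, i, j, si, sj)
    og = OverlapGraph(vertices)
    fams = sorted(vertices)
    for a in range(len(fams)):
        for b in range(a + 1, len(fams)):
            u, v = vertices[fams[a]], vertices[fams[b]]
            og_edges_add(og, u, v)
    return og


def og_edges_add(og: OverlapGraph, u: OverlapVertex, v: OverlapVertex) -> None:
    if _properly_cross(u.interval, v.interval):
        og.edges.add(frozenset({u.family, v.family}))


def _properly_cross(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (a1, a2), (b1, b2) = sorted((a, b))
    return a1 < b1 < a2 < b2


def orientation_status(og: OverlapGraph) -> tuple[str, list[frozenset[int]]]:
    """``("oriented", [])`` or ``("unoriented", offending_components)``.

    Components whose vertices are all sorted are vacuously fine.
    """
    offending = []
    for comp in og.components():
        verts = [og.vertices[f] for f in comp]
        if all(v.sorted for v in verts):
            continue
        if not any(v.oriented for v in verts):
            offending.append(comp)
    return ("unoriented" if offending else "oriented", offending)


def is_oriented(g: Genome) -> bool:
    return orientation_status(build_overlap_graph(g))[0] == "oriented"


# ---------------------------------------------------------------------------
# sorting reversals
# ---------------------------------------------------------------------------

def _require_oriented_vertex(og: OverlapGraph, family: int) -> OverlapVertex:
    v = og.vertices.get(family)
    if v is None:
        raise KeyError(family)
    if v.sorted or not v.oriented:
        raise UnorientedVertex(f"couple {family} is not an oriented unsorted vertex")
    return v


def apply_rho(g: Genome, family: int, variant: str = "rho") -> Genome:
    """Apply the sorting reversal of an oriented couple.

    ``rho`` reverses positions ``i+1 .. j``; ``rho_bar`` reverses
    ``i .. j-1`` (copies at positions ``i < j``).  Either way the couple
    forms a dedoubled adjacency afterwards.
    """
    og = build_overlap_graph(g)
    v = _require_oriented_vertex(og, family)
    if variant == "rho":
        out = reverse_segment(g, 0, v.left + 1, v.right)
    elif variant == "rho_bar":
        out = reverse_segment(g, 0, v.left, v.right - 1)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    check = build_overlap_graph(out).vertices[family]
    if not check.sorted:  # pragma: no cover - guaranteed by construction
        raise InternalError(f"rho failed to sort couple {family}")
    return out


def vertex_score(g: Genome, family: int) -> int:
    """Number of oriented (unsorted) vertices after applying the
    sorting reversal of ``family``; identical for rho and rho_bar."""
    after = build_overlap_graph(apply_rho(g, family, "rho"))
    return sum(1 for v in after.vertices.values() if v.oriented and not v.sorted)


def transform_reversal(og: OverlapGraph, start: int, end: int) -> OverlapGraph:
    """Overlap graph after reversing positions ``start..end``, computed
    from the graph's own interval data (positions and signs are remapped
    arithmetically, crossings recomputed) — a genome-free route used to
    cross-check :func:`build_overlap_graph` after any reversal."""

    def remap(pos: int, sign: int) -> tuple[int, int]:
        if start <= pos <= end:
            return (start + end - pos, -sign)
        return (pos, sign)

    vertices: dict[int, OverlapVertex] = {}
    for f, u in og.vertices.items():
        (p, sp) = remap(u.left, u.left_sign)
        (q, sq) = remap(u.right, u.right_sign)
        if p > q:
            p, q, sp, sq = q, p, sq, sp
        vertices[f] = OverlapVertex(f, p, q, sp, sq)
    out = OverlapGraph(vertices)
    fams = sorted(vertices)
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            og_edges_add(out, vertices[fams[i]], vertices[fams[j]])
    return out


def local_complement(og: OverlapGraph, family: int, variant: str = "rho") -> OverlapGraph:
    """Graph-transform route of a sorting reversal, without the genome.

    Intervals and signs are remapped arithmetically under the reversal;
    edges inside the closed neighbourhood of the vertex are complemented
    and the orientations of the neighbourhood flip.  Vertices that end
    up sorted are isolated.  Used as an independent cross-check of
    :func:`build_overlap_graph` after :func:`apply_rho`.
    """
    v = _require_oriented_vertex(og, family)
    a, b = (v.left + 1, v.right) if variant == "rho" else (v.left, v.right - 1)

    def remap(pos: int, sign: int) -> tuple[int, int]:
        if a <= pos <= b:
            return (a + b - pos, -sign)
        return (pos, sign)

    new_vertices: dict[int, OverlapVertex] = {}
    for f, u in og.vertices.items():
        (p, sp) = remap(u.left, u.left_sign)
        (q, sq) = remap(u.right, u.right_sign)
        if p > q:
            p, q, sp, sq = q, p, sq, sp
        new_vertices[f] = OverlapVertex(f, p, q, sp, sq)

    closed = og.neighbors(family) | {family}
    edges = set(og.edges)
    members = sorted(closed)
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            e = frozenset({members[i], members[j]})
            if e in edges:
                edges.discard(e)
            else:
                edges.add(e)
    # sorted vertices are isolated: drop their stale incidences
    for f, u in new_vertices.items():
        if u.sorted:
            edges = {e for e in edges if f not in e}
    return OverlapGraph(new_vertices, edges)


# ---------------------------------------------------------------------------
# distance and sorting
# ---------------------------------------------------------------------------

def reversal_distance(g: Genome, method: str = "exact",
                      limit: int = DEFAULT_EXACT_LIMIT) -> DistanceReport:
    """Reversal dedoubling distance ``n - C + 2m`` of an oriented
    genome (``n - C`` when the path is valid, i.e. m = 0)."""
    status, offending = orientation_status(build_overlap_graph(g))
    if status != "oriented":
        raise UnorientedGenomeError(
            f"unoriented components {sorted(map(sorted, offending))}: "
            "reversal dedoubling of unoriented genomes is unsupported")
    rep = dcj_distance_linear(g, method, limit)
    return replace(rep, model="reversal")


def _span_reversal_op(g: Genome, start: int, end: int) -> RearrangementOp:
    """Reversal of positions ``start..end`` as an explicit operation."""
    ms = g.chromosomes[0].markers
    left = Adjacency(ms[start - 2] if start > 1 else TELOMERE, ms[start - 1])
    right = Adjacency(ms[end - 1], ms[end] if end < len(ms) else TELOMERE)
    return make_reversal(g, left, right)


def _merge_reversal(state: Genome, cyc: GraphElement, path: GraphElement,
                    ) -> list[tuple[int, int]]:
    """Candidate spans for a merging reversal: one cut in the cycle, one
    in the path, ordered by increasing reversed span."""
    ms = state.chromosomes[0].markers
    gap_of: dict[Adjacency, int] = {}
    for i in range(len(ms) + 1):
        left = ms[i - 1] if i > 0 else TELOMERE
        right = ms[i] if i < len(ms) else TELOMERE
        gap_of[Adjacency(left, right)] = i
    spans = []
    for u in cyc.vertices:
        for w in path.vertices:
            gu, gw = gap_of[u], gap_of[w]
            if gu == gw:
                continue
            lo, hi = min(gu, gw), max(gu, gw)
            spans.append((hi - lo, lo + 1, hi))
    spans.sort()
    return [(s, e) for (_, s, e) in spans]


def reversal_sort(g: Genome, method: str = "exact",
                  limit: int = DEFAULT_EXACT_LIMIT,
                  ) -> tuple[Scenario, Genome, DistanceReport]:
    """Minimum-length reversal scenario dedoubling an oriented genome.

    Phase 1 merges every cycle outside the selected independent set
    into the path; phase 2 repeatedly applies the sorting reversal of a
    maximum-score oriented vertex.  Every accepted step keeps the
    genome oriented, and with the exact method decreases the exact
    distance by one; both properties are verified at run time.
    """
    report = reversal_distance(g, method, limit)
    state = g
    ops: list[RearrangementOp] = []
    guard = report.distance + 2 * report.n + 4

    def exact_d(x: Genome) -> int:
        return dcj_distance_linear(x, "exact", max(limit, 50)).distance

    while not is_dedoubled(state):
        if len(ops) > guard:
            raise InternalError("reversal sort exceeded its step budget")
        graph = build_adjacency_graph(state)
        sel = max_independent_cycles(build_conflict_graph(graph), method=method,
                                     limit=max(limit, 50))
        selected = {id(el) for el in sel.selected}
        nonsel = sorted((c for c in graph.cycles if id(c) not in selected),
                        key=GraphElement.sort_key)
        d_before = exact_d(state) if method == "exact" else None
        accepted = None
        if nonsel:
            # phase 1: merging reversal (never strands an unoriented component)
            path = graph.paths[0]
            for cyc in nonsel:
                for (s, e) in _merge_reversal(state, cyc, path):
                    succ = reverse_segment(state, 0, s, e)
                    if not is_oriented(succ):
                        continue
                    if d_before is not None and exact_d(succ) != d_before - 1:
                        continue
                    accepted = (_span_reversal_op(state, s, e), succ)
                    break
                if accepted:
                    break
        else:
            # phase 2: maximum-score sorting reversal
            og = build_overlap_graph(state)
            cands = sorted(
                (f for f, v in og.vertices.items() if v.oriented and not v.sorted),
                key=lambda f: (-vertex_score(state, f), f))
            for f in cands:
                v = og.vertices[f]
                for variant, (s, e) in (("rho", (v.left + 1, v.right)),
                                        ("rho_bar", (v.left, v.right - 1))):
                    succ = reverse_segment(state, 0, s, e)
                    if not is_oriented(succ):
                        continue
                    if d_before is not None and exact_d(succ) != d_before - 1:
                        continue
                    accepted = (_span_reversal_op(state, s, e), succ)
                    break
                if accepted:
                    break
        if accepted is None:
            raise InternalError("no safe reversal found; orientation theory violated")
        op, state = accepted
        ops.append(op)
    if method == "exact" and len(ops) != report.distance:
        raise InternalError("reversal scenario length differs from n - C + 2m")
    final = replace(report, distance=len(ops))
    return Scenario(ops), state, final


def to_dot(og: OverlapGraph) -> str:
    """DOT export of the overlap graph; oriented vertices are grey."""
    lines = ["graph overlap_graph {"]
    for f, v in sorted(og.vertices.items()):
        style = ' style=filled fillcolor=gray' if v.oriented else ""
        shape = ' shape=box' if v.sorted else ""
        lines.append(f'  n{f} [label="{f} [{v.left},{v.right}]"{style}{shape}];')
    for e in sorted(og.edges, key=sorted):
        a, b = sorted(e)
        lines.append(f"  n{a} -- n{b};")
    lines.append("}")
    return "\n".join(lines) + "\n"
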