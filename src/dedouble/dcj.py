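"""DCJ dedoubling: distances and scenarios.

For a totally duplicated genome G with n couples, the minimum number of
DCJ operations turning G into a dedoubled genome is ``n - C_i``, where
C_i is the maximum number of pairwise independent non-duplicated cycles
of the adjacency graph A(G).  When both G and the target are required
to be a single linear chromosome the distance becomes ``n - C + 2m``
with C the number of cycles of A(G) and m = C - C_i the number of
cycles that must be merged into the path.

The general sorter is constructive: cycles of the selected independent
set are resolved internally (each DCJ extracts one couple as a
self-loop), and every couple not covered by the selection is sorted by
one DCJ on the endpoints of one of its edges.  Every emitted operation
decreases the exact distance by one; this is asserted at run time.

The single-linear sorter additionally merges the non-selected cycles
into the path and chooses rejoins so that every transiently excised
circular intermediate is reabsorbed before the end.  Rejoin choices are
found by a depth-first search over the constructive moves, bounded by
the exact distance, so the emitted scenario always meets the formula.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import genome as gm
from .adjacency_graph import AdjacencyGraph, Edge, GraphElement, build_adjacency_graph
from .cycle_selection import (
    DEFAULT_EXACT_LIMIT,
    SelectionResult,
    build_conflict_graph,
    max_independent_cycles,
    merge_count,
)
from .errors import InternalError, NotUnichromosomal
from .genome import Adjacency, Genome, adjacency_from_extremities, is_dedoubled
from .rearrange import OpKind, RearrangementOp, Scenario, apply_dcj


@dataclass
class DistanceReport:
    """Summary of a dedoubling distance computation."""

    n: int
    C: int
    C_i: int
    m: int | None
    distance: int
    model: str  # "dcj" | "dcj_linear" | "reversal"
    method: str  # "exact" | "greedy"

    def as_dict(self) -> dict:
        return {"n": self.n, "C": self.C, "C_i": self.C_i, "m": self.m,
                "distance": self.distance, "model": self.model, "method": self.method}


def _analyze(g: Genome, method: str, limit: int) -> tuple[AdjacencyGraph, SelectionResult]:
    graph = build_adjacency_graph(g)
    cg = build_conflict_graph(graph)
    sel = max_independent_cycles(cg, method=method, limit=limit)
    return graph, sel


def dcj_distance(g: Genome, method: str = "exact",
                 limit: int = DEFAULT_EXACT_LIMIT) -> DistanceReport:
    """DCJ dedoubling distance ``n - C_i`` of a totally duplicated genome."""
    graph, sel = _analyze(g, method, limit)
    n = graph.n
    return DistanceReport(n=n, C=len(graph.cycles), C_i=sel.size, m=None,
                          distance=n - sel.size, model="dcj", method=method)


def dcj_distance_linear(g: Genome, method: str = "exact",
                        limit: int = DEFAULT_EXACT_LIMIT) -> DistanceReport:
    """Minimum DCJ scenario length from a single linear chromosome to a
    dedoubled genome that is again a single linear chromosome:
    ``n - C + 2m``."""
    if not g.unichromosomal_linear:
        raise NotUnichromosomal("dcj_distance_linear needs one linear chromosome")
    graph, sel = _analyze(g, method, limit)
    m = merge_count(graph, sel)
    n, c = graph.n, len(graph.cycles)
    return DistanceReport(n=n, C=c, C_i=sel.size, m=m,
                          distance=n - c + 2 * m, model="dcj_linear", method=method)


# ---------------------------------------------------------------------------
# constructive sorting
# ---------------------------------------------------------------------------

def _resolution_op(graph: AdjacencyGraph, edge: Edge) -> RearrangementOp:
    """The DCJ cutting the two endpoint adjacencies of ``edge`` and
    rejoining so that the couple forms its dedoubled adjacency (a
    self-loop of A); the two leftover extremities are glued together."""
    u, v = edge.endpoints()
    assert u != v, "resolution needs an unsorted couple"
    e1, e2 = edge.extremity_pair()
    new1 = adjacency_from_extremities(e1, e2)
    rest = [e for e in (*u.extremities(), *v.extremities()) if e not in (e1, e2)]
    if len(rest) == 2:
        new2 = adjacency_from_extremities(rest[0], rest[1])
    elif len(rest) == 1:
        new2 = adjacency_from_extremities(rest[0], None)
    else:
        new2 = None
    return RearrangementOp(OpKind.DCJ, u, v, new1, new2)


def _covered_families(sel: SelectionResult) -> set[int]:
    out: set[int] = set()
    for el in sel.selected:
        out |= el.couple_set
    return out


def _unsorted_families(g: Genome) -> set[int]:
    adjset = gm.adjacencies(g)
    out = set()
    for f in g.duplicated_families():
        forms = gm.dedoubled_adjacency_forms(f)
        if forms[0] not in adjset and forms[1] not in adjset:
            out.add(f)
    return out


def _constructive_step(graph: AdjacencyGraph, sel: SelectionResult) -> RearrangementOp:
    """One distance-decreasing DCJ: extract a self-loop from a selected
    cycle if one still has several couples, otherwise sort the smallest
    uncovered couple on the endpoints of its head edge."""
    big = sorted((el for el in sel.selected if el.size >= 2), key=GraphElement.sort_key)
    if big:
        edge = min(big[0].edges, key=Edge.sort_key)
        return _resolution_op(graph, edge)
    covered = _covered_families(sel)
    unsorted = _unsorted_families(graph.genome)
    targets = sorted(unsorted - covered)
    if not targets:
        raise InternalError("no constructive move although genome is not dedoubled")
    edge = graph.edge(targets[0], "head")
    return _resolution_op(graph, edge)


def dcj_sort(g: Genome, method: str = "exact", limit: int = DEFAULT_EXACT_LIMIT,
             ) -> tuple[Scenario, Genome, DistanceReport]:
    """Minimum-length DCJ scenario transforming ``g`` into a dedoubled
    genome (Algorithm-1 style construction).

    Returns ``(scenario, end_genome, report)``; with the exact method
    the scenario length equals ``n - C_i`` and every prefix decreases
    the remaining exact distance by one.
    """
    report = dcj_distance(g, method, limit)
    ops: list[RearrangementOp] = []
    state = g
    remaining = dcj_distance(state, "exact", limit).distance if method == "exact" else None
    while not is_dedoubled(state):
        graph = build_adjacency_graph(state)
        cg = build_conflict_graph(graph)
        sel = max_independent_cycles(cg, method=method, limit=limit)
        op = _constructive_step(graph, sel)
        state = apply_dcj(state, op)
        ops.append(op)
        if method == "exact":
            now = dcj_distance(state, "exact", limit).distance
            if now != remaining - 1:
                raise InternalError(
                    f"step {len(ops)} changed exact distance {remaining} -> {now}")
            remaining = now
    if method == "exact" and len(ops) != report.distance:
        raise InternalError("scenario length differs from n - C_i")
    final = DistanceReport(report.n, report.C, report.C_i, report.m,
                           len(ops), report.model, method)
    return Scenario(ops), state, final


# ---------------------------------------------------------------------------
# single-linear sorting
# ---------------------------------------------------------------------------

def _state_key(g: Genome) -> tuple:
    return tuple(sorted(gm._chrom_canonical(c) for c in g.chromosomes))


def _merge_ops(state: Genome, graph: AdjacencyGraph, sel: SelectionResult):
    """Candidate merging DCJs: one cut in a non-selected cycle, one in
    the path, rejoined without splitting chromosomes.  Ordered so that
    the shortest same-chromosome reversal comes first."""
    selected = {id(el) for el in sel.selected}
    paths = graph.paths
    if not paths:
        return
    path_vertices = sorted(paths[0].vertices, key=Adjacency.sort_key)
    for cyc in sorted((c for c in graph.cycles if id(c) not in selected),
                      key=GraphElement.sort_key):
        u = min(cyc.vertices, key=Adjacency.sort_key)
        for w in path_vertices:
            a = list(u.extremities())  # cycle vertices are internal: two slots
            b = list(w.extremities())  # path vertex may be telomeric: one slot
            if len(b) == 2:
                matchings = [[(a[0], b[0]), (a[1], b[1])],
                             [(a[0], b[1]), (a[1], b[0])]]
            else:
                matchings = [[(a[0], b[0])], [(a[1], b[0])]]
            for pairs in matchings:
                used = {x for p in pairs for x in p}
                news = [adjacency_from_extremities(x, y) for x, y in pairs]
                news += [adjacency_from_extremities(x, None)
                         for x in (*a, *b) if x not in used]
                yield RearrangementOp(OpKind.DCJ, u, w, news[0],
                                      news[1] if len(news) > 1 else None)


def _sorting_ops(state: Genome, graph: AdjacencyGraph):
    """Candidate couple-sorting DCJs: for every unsorted couple, the
    resolution through each of its two edges."""
    for f in sorted(_unsorted_families(state)):
        for which in ("head", "tail"):
            yield _resolution_op(graph, graph.edge(f, which))


def dcj_sort_linear(g: Genome, method: str = "exact",
                    limit: int = DEFAULT_EXACT_LIMIT,
                    ) -> tuple[Scenario, Genome, DistanceReport]:
    """DCJ scenario of length ``n - C + 2m`` from a single linear
    chromosome to a dedoubled single linear chromosome.

    Intermediate genomes may transiently contain circular chromosomes;
    the search guarantees they are reabsorbed and the final genome is a
    dedoubled single linear chromosome.
    """
    report = dcj_distance_linear(g, method, limit)
    budget = report.distance
    failed: dict[tuple, int] = {}

    def lower_bound(state: Genome) -> int:
        graph = build_adjacency_graph(state)
        sel = max_independent_cycles(build_conflict_graph(graph),
                                     method="exact", limit=max(limit, 50))
        return graph.n - sel.size

    def candidates(state: Genome):
        graph = build_adjacency_graph(state)
        cg = build_conflict_graph(graph)
        sel = max_independent_cycles(cg, method="exact", limit=max(limit, 50))
        ops = list(_sorting_ops(state, graph))
        # extractions from selected multi-couple cycles
        for el in sorted((e for e in sel.selected if e.size >= 2),
                         key=GraphElement.sort_key):
            ops.append(_resolution_op(graph, min(el.edges, key=Edge.sort_key)))
        merge_list = list(_merge_ops(state, graph, sel))
        scored = []
        n_chroms = len(state.chromosomes)
        for rank, op in enumerate(ops + merge_list):
            try:
                succ = apply_dcj(state, op)
            except Exception:  # noqa: BLE001 - candidate may be degenerate
                continue
            delta = len(succ.chromosomes) - n_chroms
            is_merge = rank >= len(ops)
            scored.append(((delta, is_merge, rank), op, succ))
        scored.sort(key=lambda t: t[0])
        return scored

    def search(state: Genome, remaining: int) -> list[RearrangementOp] | None:
        if is_dedoubled(state) and state.unichromosomal_linear:
            return []
        if remaining <= 0:
            return None
        key = _state_key(state)
        if failed.get(key, -1) >= remaining:
            return None
        circulars = sum(1 for c in state.chromosomes if c.circular)
        if circulars > remaining or lower_bound(state) > remaining:
            failed[key] = max(failed.get(key, -1), remaining)
            return None
        for _score, op, succ in candidates(state):
            rest = search(succ, remaining - 1)
            if rest is not None:
                return [op] + rest
        failed[key] = max(failed.get(key, -1), remaining)
        return None

    ops = search(g, budget)
    if ops is None:
        raise InternalError(
            f"no scenario of length {budget} found; the n - C + 2m bound was missed")
    state = g
    for op in ops:
        state = apply_dcj(state, op)
    if not (is_dedoubled(state) and state.unichromosomal_linear):
        raise InternalError("single-linear sort ended in a bad state")
    final = DistanceReport(report.n, report.C, report.C_i, report.m,
                           len(ops), "dcj_linear", method)
    if method == "exact" and final.distance != budget:
        raise InternalError("scenario shorter than the exact formula")
    return Scenario(ops), state, final
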