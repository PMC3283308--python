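"""Selecting a maximum set of pairwise independent non-duplicated cycles.

The dedoubling distance formulas depend on C_i, the maximum number of
non-duplicated cycles of A(G) that can be chosen so that no two share a
couple.  This is a maximum independent set on the *conflict graph*
(nodes: non-duplicated cycles; links: shared couples) — an NP-hard but
2-approximable subproblem, and tiny in practice: desk-scale genomes
yield conflict graphs of a handful of nodes.

Two solvers are provided: an exact branch-and-bound (the default, gated
by a node-count limit) and a deterministic min-degree greedy whose
solution is empirically at least half the optimum.

For a genome consisting of one linear chromosome, ``merge_count``
derives m = C - C_i, the minimum number of cycles that must be merged
into the path to make it valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .adjacency_graph import AdjacencyGraph, GraphElement
from .errors import NotUnichromosomal, SizeLimitExceeded

DEFAULT_EXACT_LIMIT = 25


@dataclass
class ConflictGraph:
    """Conflict structure over the non-duplicated cycles of A(G)."""

    nodes: list[GraphElement]
    links: dict[tuple[int, int], frozenset[int]] = field(default_factory=dict)

    def neighbors(self, i: int) -> set[int]:
        out = set()
        for (a, b) in self.links:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out

    def adjacency_lists(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.nodes]
        for (a, b) in self.links:
            adj[a].add(b)
            adj[b].add(a)
        return adj


@dataclass
class SelectionResult:
    selected: list[GraphElement]
    method: str  # "exact" | "greedy"
    certificate: str = ""

    @property
    def size(self) -> int:
        return len(self.selected)


def build_conflict_graph(graph: AdjacencyGraph) -> ConflictGraph:
    """Nodes are the non-duplicated cycles; a link joins two cycles
    sharing at least one couple."""
    nodes = [el for el in graph.cycles if not el.duplicated]
    nodes.sort(key=GraphElement.sort_key)
    cg = ConflictGraph(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            shared = nodes[i].couple_set & nodes[j].couple_set
            if shared:
                cg.links[(i, j)] = frozenset(shared)
    return cg


def max_independent_cycles(cg: ConflictGraph, method: str = "exact",
                           limit: int = DEFAULT_EXACT_LIMIT) -> SelectionResult:
    """Maximum (or greedily large) set of pairwise independent cycles.

    ``exact`` guarantees a true maximum via branch-and-bound and raises
    :class:`SizeLimitExceeded` beyond ``limit`` nodes; ``greedy`` is the
    deterministic min-degree rule.
    """
    if method == "exact":
        if len(cg.nodes) > limit:
            raise SizeLimitExceeded(
                f"{len(cg.nodes)} conflict nodes exceed exact-solver limit {limit}")
        chosen = _exact_mis(cg.adjacency_lists())
        return SelectionResult([cg.nodes[i] for i in sorted(chosen)], "exact",
                               certificate="branch-and-bound over all maximal sets")
    if method == "greedy":
        chosen = _greedy_mis(cg)
        return SelectionResult([cg.nodes[i] for i in sorted(chosen)], "greedy")
    raise ValueError(f"unknown method {method!r}")


def _exact_mis(adj: list[set[int]]) -> set[int]:
    """Branch and bound on the max-degree node; deterministic."""
    n = len(adj)
    best: set[int] = set()

    def solve(alive: set[int], chosen: set[int]) -> None:
        nonlocal best
        if len(chosen) + len(alive) <= len(best):
            return
        live_deg = {v: len(adj[v] & alive) for v in alive}
        isolated = {v for v, d in live_deg.items() if d == 0}
        if isolated:
            solve(alive - isolated, chosen | isolated)
            return
        if not alive:
            if len(chosen) > len(best):
                best = set(chosen)
            return
        v = max(sorted(alive), key=lambda x: live_deg[x])
        # include v
        solve(alive - {v} - adj[v], chosen | {v})
        # exclude v
        solve(alive - {v}, chosen)

    solve(set(range(n)), set())
    return best


def _greedy_mis(cg: ConflictGraph) -> set[int]:
    """Repeatedly take a node of minimum current degree (ties broken by
    smallest couple set, then node index) and delete its neighbors."""
    adj = cg.adjacency_lists()
    alive = set(range(len(cg.nodes)))
    chosen: set[int] = set()
    while alive:
        def key(v: int) -> tuple:
            return (len(adj[v] & alive), tuple(sorted(cg.nodes[v].couple_set)), v)
        v = min(alive, key=key)
        chosen.add(v)
        alive -= {v} | adj[v]
    return chosen


def merge_count(graph: AdjacencyGraph, selection: SelectionResult) -> int:
    """m = C - C_i: the minimum number of cycles whose merging into the
    path makes it valid.  The cycles to merge are exactly those outside
    the selected set."""
    if len(graph.paths) != 1:
        raise NotUnichromosomal(
            f"merge count needs exactly one path, found {len(graph.paths)}")
    c_total = len(graph.cycles)
    m = c_total - selection.size
    assert m >= 0
    return m
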