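"""Seeded simulators and brute-force oracles.

The simulator plays the generative model behind the dedoubling problem:
a non-duplicated ancestor evolves by k rearrangements, a configurable
fraction of which are breakpoint-duplication operations that leave a
copied marker at their breakpoints.  The derived genome (totalized if
needed) is what the solvers see; the true scenario bounds the
dedoubling distance from above.

The oracles compute exact distances by breadth-first search over
canonicalized genome states and are the independent reference for the
closed-form distances; they are only feasible for a handful of couples
and are guarded by a size limit.
"""

from __future__ import annotations

import functools
import itertools
import random
from dataclasses import dataclass, field

from . import reversal as rv
from .errors import ExhaustedResampling, SizeLimitExceeded
from .genome import (
    BAR,
    PLAIN,
    TELOMERE,
    Adjacency,
    Chromosome,
    Genome,
    Marker,
    adjacencies,
    adjacency_from_extremities,
    canonical_form,
    is_dedoubled,
    parse_genome,
    totalize,
)
from .rearrange import (
    OpKind,
    RearrangementOp,
    Scenario,
    _insert_copy,
    apply_dcj,
    apply_op,
    make_reversal,
    reversal_news,
)

DEFAULT_BD_MIX = {"bd1": 0.4, "bd2": 0.3, "plain": 0.3}


# ---------------------------------------------------------------------------
# random genomes and evolutions
# ---------------------------------------------------------------------------

def random_ancestor(n: int, chromosomes: int = 1, circular_fraction: float = 0.0,
                    seed: int | None = None) -> Genome:
    """A non-duplicated genome with families 1..n in random order and
    orientation, split over the requested number of chromosomes."""
    if n < 1:
        raise ValueError("need at least one marker")
    rng = random.Random(seed)
    fams = list(range(1, n + 1))
    rng.shuffle(fams)
    markers = [Marker(f, PLAIN, rng.choice((1, -1))) for f in fams]
    chromosomes = min(chromosomes, n)
    cuts = sorted(rng.sample(range(1, n), chromosomes - 1)) if chromosomes > 1 else []
    bounds = [0] + cuts + [n]
    chroms = []
    for a, b in zip(bounds, bounds[1:]):
        circ = rng.random() < circular_fraction
        chroms.append(Chromosome(tuple(markers[a:b]), circular=circ))
    return Genome(tuple(chroms))


@dataclass
class SimulationRecord:
    ancestor: Genome
    scenario: Scenario
    derived: Genome
    seed: int | None
    parameters: dict = field(default_factory=dict)


def _random_dcj_op(state: Genome, rng: random.Random) -> RearrangementOp | None:
    adjs = sorted(adjacencies(state), key=Adjacency.sort_key)
    if len(adjs) < 2:
        return None
    a1, a2 = rng.sample(adjs, 2)
    news = _random_rejoin(a1, a2, rng)
    return RearrangementOp(OpKind.DCJ, a1, a2, news[0],
                           news[1] if len(news) > 1 else None)


def _random_rejoin(a1: Adjacency, a2: Adjacency, rng: random.Random) -> list[Adjacency]:
    e1 = list(a1.extremities())
    e2 = list(a2.extremities())
    if len(e2) == 2 and rng.random() < 0.5:
        e2 = e2[::-1]
    elif len(e2) == 1 and len(e1) == 2 and rng.random() < 0.5:
        e1 = e1[::-1]
    pairs = list(zip(e1, e2))
    used = {x for p in pairs for x in p}
    news = [adjacency_from_extremities(x, y) for x, y in pairs]
    news += [adjacency_from_extremities(x, None)
             for x in (*e1, *e2) if x not in used]
    return news


def _random_reversal_op(state: Genome, rng: random.Random) -> RearrangementOp | None:
    ms = state.chromosomes[0].markers
    if len(ms) < 1:
        return None
    s = rng.randrange(1, len(ms) + 1)
    e = rng.randrange(s, len(ms) + 1)
    left = Adjacency(ms[s - 2] if s > 1 else TELOMERE, ms[s - 1])
    right = Adjacency(ms[e - 1], ms[e] if e < len(ms) else TELOMERE)
    if left == right:
        return None
    return make_reversal(state, left, right)


def _eligible_sides(state: Genome) -> list[tuple[Adjacency, Marker, bool]]:
    """(adjacency, oriented marker, is_left) triples whose marker family
    is still single-copy: candidates for a breakpoint duplication."""
    counts = state.family_counts()
    out = []
    for adj in sorted(adjacencies(state), key=Adjacency.sort_key):
        for side, is_left in ((adj.left, True), (adj.right, False)):
            if side is TELOMERE or counts.get(side.family, 0) != 1:
                continue
            out.append((adj, side, is_left))
    return out


def _dup_pattern(marker: Marker, is_left: bool) -> Adjacency:
    """Post-insertion cut adjacency for duplicating a marker at a
    breakpoint: the copy lands on the far side of the cut, so a marker
    on the left of its adjacency yields pattern ``(x x')`` and one on
    the right yields ``(x' x)``."""
    other = marker.with_copy(1 - marker.copy)
    return Adjacency(marker, other) if is_left else Adjacency(other, marker)


def _random_bd_op(state: Genome, rng: random.Random, model: str,
                  kind: str) -> RearrangementOp | None:
    sides = _eligible_sides(state)
    if not sides:
        return None
    if kind == "bd2":
        # two distinct adjacencies duplicating distinct families
        pool = sides[:]
        rng.shuffle(pool)
        for (adj1, m1, l1), (adj2, m2, l2) in itertools.combinations(pool, 2):
            if adj1 != adj2 and m1.family != m2.family:
                break
        else:
            return None
        cut1, cut2 = _dup_pattern(m1, l1), _dup_pattern(m2, l2)
        mid = _insert_copy(_insert_copy(state, cut1, m1.family), cut2, m2.family)
        dups = (m1.family, m2.family)
    else:
        adj1, m1, l1 = rng.choice(sides)
        cut1 = _dup_pattern(m1, l1)
        mid = _insert_copy(state, cut1, m1.family)
        others = [a for a in sorted(adjacencies(mid), key=Adjacency.sort_key)
                  if a != cut1]
        if not others:
            return None
        cut2 = rng.choice(others)
        dups = (m1.family,)
    if model == "reversal":
        try:
            n1, n2 = reversal_news(mid, cut1, cut2)
        except Exception:  # noqa: BLE001 - e.g. same gap; caller redraws
            return None
        news = [n1, n2]
        opkind = OpKind.BD1_REVERSAL if len(dups) == 1 else OpKind.BD2_REVERSAL
    else:
        news = _random_rejoin(cut1, cut2, rng)
        opkind = OpKind.BD1_DCJ if len(dups) == 1 else OpKind.BD2_DCJ
    return RearrangementOp(opkind, cut1, cut2, news[0],
                           news[1] if len(news) > 1 else None, dups)


def random_bd_evolution(ancestor: Genome, k: int, model: str = "dcj",
                        seed: int | None = None,
                        mix: dict | None = None,
                        oriented_only: bool = False,
                        max_resample: int = 200) -> SimulationRecord:
    """Evolve ``ancestor`` by ``k`` operations drawn from the BD mix.

    ``model="reversal"`` draws only (BD-)reversals, so the ancestor must
    be a single linear chromosome.  With ``oriented_only`` the evolution
    is redrawn until the totalized derived genome is oriented.
    """
    mix = dict(DEFAULT_BD_MIX if mix is None else mix)
    base = random.Random(seed)
    for attempt in range(max_resample):
        rng = random.Random(base.randrange(2 ** 31))
        state = ancestor
        ops: list[RearrangementOp] = []
        for _ in range(k):
            op = None
            for _retry in range(40):
                r = rng.random()
                if r < mix["bd1"]:
                    op = _random_bd_op(state, rng, model, "bd1")
                elif r < mix["bd1"] + mix["bd2"]:
                    op = _random_bd_op(state, rng, model, "bd2")
                elif model == "reversal":
                    op = _random_reversal_op(state, rng)
                else:
                    op = _random_dcj_op(state, rng)
                if op is not None:
                    break
            if op is None:
                break
            state = apply_op(state, op)
            ops.append(op)
        record = SimulationRecord(ancestor, Scenario(ops), state, seed,
                                  {"k": k, "model": model, "mix": mix,
                                   "oriented_only": oriented_only})
        if not oriented_only:
            return record
        total, _ = totalize(state)
        if total.unichromosomal_linear and rv.is_oriented(total):
            return record
    raise ExhaustedResampling(
        f"no admissible evolution found in {max_resample} draws")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def all_dcj_ops(g: Genome):
    """Every DCJ applicable to ``g``: both crosswise rejoins of every
    pair of adjacencies."""
    adjs = sorted(adjacencies(g), key=Adjacency.sort_key)
    for a1, a2 in itertools.combinations(adjs, 2):
        e1 = list(a1.extremities())
        e2 = list(a2.extremities())
        if len(e1) == 1 and len(e2) == 2:
            e1, e2 = e2, e1
        if len(e2) == 2:
            matchings = [[(e1[0], e2[0]), (e1[1], e2[1])],
                         [(e1[0], e2[1]), (e1[1], e2[0])]]
        elif len(e1) == 2:
            matchings = [[(e1[0], e2[0])], [(e1[1], e2[0])]]
        else:
            matchings = [[(e1[0], e2[0])]]
        for pairs in matchings:
            used = {x for p in pairs for x in p}
            news = [adjacency_from_extremities(x, y) for x, y in pairs]
            news += [adjacency_from_extremities(x, None)
                     for x in (*e1, *e2) if x not in used]
            yield RearrangementOp(OpKind.DCJ, a1, a2, news[0],
                                  news[1] if len(news) > 1 else None)


def all_dcj_successors(g: Genome):
    """Every genome reachable by one DCJ."""
    for op in all_dcj_ops(g):
        yield apply_dcj(g, op)


def all_reversal_successors(g: Genome):
    ms = g.chromosomes[0].markers
    for s in range(1, len(ms) + 1):
        for e in range(s, len(ms) + 1):
            if s == 1 and e == len(ms):
                continue  # full flip: same genome up to reading direction
            from .rearrange import reverse_segment
            yield reverse_segment(g, 0, s, e)


def _dedoubled_goal_states(g: Genome, single_linear: bool):
    """All dedoubled genomes over the marker content of ``g`` (couples
    in sorted form, single-copy markers free), canonicalized."""
    counts = g.family_counts()
    couples = tuple(sorted(f for f, c in counts.items() if c == 2))
    singles = tuple(sorted(f for f, c in counts.items() if c == 1))
    return _goal_states_cached(couples, singles, single_linear)


@functools.lru_cache(maxsize=64)
def _goal_states_cached(couples: tuple[int, ...], singles: tuple[int, ...],
                        single_linear: bool):
    units = []
    for f in couples:
        units.append((
            (Marker(f, PLAIN, 1), Marker(f, BAR, 1)),       # (x x')
            (Marker(f, BAR, 1), Marker(f, PLAIN, 1)),       # (x' x)
        ))
    for f in singles:
        units.append(((Marker(f, PLAIN, 1),),))
    goals: set[tuple] = set()

    def place(seq_of_units):
        """All genomes arranging the given unit sequence blocks."""
        n = len(seq_of_units)
        for perm in itertools.permutations(range(n)):
            for signs in itertools.product((1, -1), repeat=n):
                blocks = []
                for idx, sg in zip(perm, signs):
                    u = seq_of_units[idx]
                    blocks.append(tuple(u) if sg > 0 else tuple(-m for m in reversed(u)))
                if single_linear:
                    flat = tuple(m for b in blocks for m in b)
                    yield Genome((Chromosome(flat, circular=False),))
                else:
                    for cuts in itertools.product((0, 1), repeat=n - 1):
                        groups = []
                        cur = [blocks[0]]
                        for b, c in zip(blocks[1:], cuts):
                            if c:
                                groups.append(cur)
                                cur = [b]
                            else:
                                cur.append(b)
                        groups.append(cur)
                        for shapes in itertools.product((False, True), repeat=len(groups)):
                            chroms = []
                            for grp, circ in zip(groups, shapes):
                                flat = tuple(m for b in grp for m in b)
                                chroms.append(Chromosome(flat, circular=circ))
                            yield Genome(tuple(chroms))

    for combo in itertools.product(*units):
        for goal in place(list(combo)):
            goals.add(canonical_form(goal))
    return goals


def bfs_oracle(g: Genome, model: str = "dcj", limit: int = 3) -> int:
    """Exact distance to the nearest dedoubled genome by bidirectional
    breadth-first search over canonicalized states.

    Models: ``dcj`` (any dedoubled end state), ``dcj_linear`` (end state
    must be one linear chromosome), ``reversal`` (reversals only, hence
    single linear throughout).  Guarded by ``limit`` on the number of
    couples.
    """
    size = sum(1 for _ in g.markers())
    if size > 2 * limit:
        raise SizeLimitExceeded(f"{size} markers exceed oracle limit {2 * limit}")
    if model in ("dcj_linear", "reversal") and not g.unichromosomal_linear:
        raise ValueError(f"model {model} needs a single linear chromosome")
    if model == "dcj":
        succ = all_dcj_successors
        goals = _dedoubled_goal_states(g, single_linear=False)
    elif model == "dcj_linear":
        succ = all_dcj_successors
        goals = _dedoubled_goal_states(g, single_linear=True)
    elif model == "reversal":
        succ = all_reversal_successors
        goals = _dedoubled_goal_states(g, single_linear=True)
    else:
        raise ValueError(f"unknown model {model!r}")
    return _bidirectional_bfs(g, goals, succ)


def _bidirectional_bfs(start: Genome, goal_keys: set, succ) -> int:
    """Shortest number of operations from ``start`` to any goal.

    The DCJ and reversal successor relations are symmetric (every
    operation has an inverse of the same kind), so the goal side can be
    expanded with the forward relation.  Levels are expanded alternately
    (smaller frontier first); once a level expansion produces a meeting
    state, ``depth_here + recorded_depth_there`` is minimal, because any
    shorter path would have met within the levels already completed.
    """
    start_key = canonical_form(start)
    if start_key in goal_keys:
        return 0
    fwd: dict[tuple, Genome] = {start_key: start}
    bwd: dict[tuple, Genome] = {k: _genome_from_key(k) for k in goal_keys}
    fwd_depth: dict[tuple, int] = {start_key: 0}
    bwd_depth: dict[tuple, int] = {k: 0 for k in goal_keys}
    df = db = 0

    while fwd and bwd:
        if len(fwd) <= len(bwd):
            frontier, seen, other, depth = fwd, fwd_depth, bwd_depth, df + 1
            df += 1
        else:
            frontier, seen, other, depth = bwd, bwd_depth, fwd_depth, db + 1
            db += 1
        new: dict[tuple, Genome] = {}
        best = None
        for genome_ in frontier.values():
            for s in succ(genome_):
                key = canonical_form(s)
                if key in other:
                    cand = depth + other[key]
                    if best is None or cand < best:
                        best = cand
                if key not in seen:
                    seen[key] = depth
                    new[key] = s
        if best is not None:
            return best
        if frontier is fwd:
            fwd = new
        else:
            bwd = new
    raise SizeLimitExceeded("search space exhausted without reaching a goal")


def _genome_from_key(key: tuple) -> Genome:
    chroms = []
    for entry in key:
        shape, body = entry[0], entry[1:]
        chroms.append(Chromosome(tuple(Marker(f, c, s) for (f, c, s) in body),
                                 circular=shape == "C"))
    return Genome(tuple(chroms))


def enumerate_totally_duplicated(n: int, unichromosomal_linear: bool = False):
    """All totally duplicated genomes with couples 1..n, one per
    symmetry class (reading direction, rotation, chromosome order,
    copy-label swap).  Exhaustive-oracle fodder; keep n tiny."""
    markers = [Marker(f, c, 1) for f in range(1, n + 1) for c in (PLAIN, BAR)]
    seen: set[tuple] = set()
    total = len(markers)
    for perm in itertools.permutations(markers):
        for signs in itertools.product((1, -1), repeat=total):
            seq = tuple(Marker(m.family, m.copy, s) for m, s in zip(perm, signs))
            if unichromosomal_linear:
                splits = [((len(seq),), (False,))]
            else:
                splits = []
                for cuts in itertools.product((0, 1), repeat=total - 1):
                    sizes = []
                    run = 1
                    for c in cuts:
                        if c:
                            sizes.append(run)
                            run = 1
                        else:
                            run += 1
                    sizes.append(run)
                    for shapes in itertools.product((False, True), repeat=len(sizes)):
                        splits.append((tuple(sizes), shapes))
            for sizes, shapes in splits:
                chroms = []
                pos = 0
                for size, circ in zip(sizes, shapes):
                    chroms.append(Chromosome(seq[pos:pos + size], circular=circ))
                    pos += size
                g = Genome(tuple(chroms))
                key = canonical_form(g)
                if key not in seen:
                    seen.add(key)
                    yield g


def _remove_copy(g: Genome, family: int, copy: int) -> Genome:
    chroms = []
    for chrom in g:
        out = tuple(m for m in chrom.markers
                    if not (m.family == family and m.copy == copy))
        if out:
            chroms.append(Chromosome(out, chrom.circular))
    return Genome(tuple(chroms))


def bd_dcj_oracle(g: Genome, limit: int = 4) -> int:
    """Minimum BD-DCJ scenario length from *some* non-duplicated genome
    to ``g``, by breadth-first search over inverse operations.

    An inverse plain DCJ is a DCJ; an inverse BD-DCJ is a DCJ whose
    re-formed adjacencies include one or two duplication patterns
    ``(x x')``, whose adjacent copy is then deleted.  The goal is any
    genome with no duplicated family.  Independent of the adjacency
    graph machinery; feasible only for a handful of families.
    """
    from .rearrange import _is_dup_pattern

    if len(g.family_counts()) > 2 * limit:
        raise SizeLimitExceeded(f"too many families for the BD oracle")

    def inverse_successors(state: Genome):
        for op in all_dcj_ops(state):
            res = apply_dcj(state, op)
            yield res  # inverse of a plain DCJ
            patterns = []
            for new in (op.new1, op.new2):
                if new is None:
                    continue
                fam = new.left.family if new.left is not TELOMERE else None
                if fam is not None and _is_dup_pattern(new, fam):
                    bar = new.left if new.left.copy == BAR else new.right
                    patterns.append((fam, bar.copy))
            # inverse 1-BD: drop either pattern's copy; inverse 2-BD: both
            for (fam, copy) in patterns:
                yield _remove_copy(res, fam, copy)
            if len(patterns) == 2:
                both = res
                for (fam, copy) in patterns:
                    both = _remove_copy(both, fam, copy)
                yield both

    def non_duplicated(state: Genome) -> bool:
        return not state.duplicated_families()

    if non_duplicated(g):
        return 0
    frontier = {canonical_form(g): g}
    seen = set(frontier)
    depth = 0
    while frontier:
        depth += 1
        new: dict[tuple, Genome] = {}
        for state in frontier.values():
            for s in inverse_successors(state):
                if non_duplicated(s):
                    return depth
                key = canonical_form(s)
                if key not in seen:
                    seen.add(key)
                    new[key] = s
        frontier = new
    raise SizeLimitExceeded("inverse search exhausted")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

#: the published 26-marker single-chromosome worked example: letters
#: A..M mapped to families 1..13, second occurrence of each letter as
#: the bar copy, signs as printed.
PUBLISHED_EXAMPLE_TEXT = ("L 1 -2 -1' -2' 3 4 -3' -5 -6 -4' 7 -8 -7' 8' "
              "9 -10 -6' -5' -9' 10' 11 -12 -13 -11' -12' -13'")

_EXAMPLES = {
    "E1": "L 1 1' 2 2'",        # dedoubled
    "E2": "L 1 -1' 2 2'",       # oriented, one reversal from sorted
    "E3": "L 1 2 1' 2'",        # unoriented valid path
    "E4": "L 1 2 2' 1'",        # non-valid path, one merge needed
    "E5": "L 1 -2 -1' -2'",     # oriented, crossing couples
    "E6": "C 1 2 1' 2'",        # circular, duplicated cycle
    "published26": PUBLISHED_EXAMPLE_TEXT,
}


def worked_fixtures() -> dict[str, Genome]:
    """Named worked-example genomes, including the published 26-marker one."""
    return {name: parse_genome(text) for name, text in _EXAMPLES.items()}
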