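"""Rearrangement operations: DCJ, reversal, and breakpoint-duplication.

A DCJ cuts two different adjacencies and glues pairs of the four exposed
extremities into two new adjacencies; a reversal is the DCJ whose rejoin
inverts the segment between its two cuts on one chromosome.

A breakpoint-duplication (BD) operation first copies one marker per
designated breakpoint — the copy is inserted next to its original so the
two flank the cut, e.g. ``(a b)`` becomes ``a a' | b`` — and then applies
an ordinary DCJ (or reversal) on the modified adjacencies.  This is the
mechanism that leaves (possibly inverted) duplicated segments on both
sides of a rearrangement breakpoint.

Operations are stored with explicit cut and new adjacencies, so a
scenario replays bit-exactly.  For BD kinds the recorded cuts are the
*post-insertion* ones (``(a a')`` patterns); the insertion position is
recovered from them at apply time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import genome as gm
from .errors import (
    AdjacencyNotFound,
    AlreadyDuplicated,
    CutsOnDifferentChromosomes,
    IdenticalCuts,
    InvalidRejoin,
    ParseError,
    ScenarioInvalidAtStep,
)
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
    genome_from_adjacencies,
)


class OpKind(enum.Enum):
    DCJ = "DCJ"
    REVERSAL = "REVERSAL"
    BD1_DCJ = "BD1_DCJ"
    BD2_DCJ = "BD2_DCJ"
    BD1_REVERSAL = "BD1_REVERSAL"
    BD2_REVERSAL = "BD2_REVERSAL"

    @property
    def is_bd(self) -> bool:
        return self.name.startswith("BD")

    @property
    def is_reversal(self) -> bool:
        return self.name.endswith("REVERSAL")


@dataclass(frozen=True)
class RearrangementOp:
    """One rearrangement step.

    ``cut1``/``cut2`` are the adjacencies destroyed by the DCJ second
    step (for BD kinds these already contain the inserted copy);
    ``new1``/``new2`` are the adjacencies created (``new2`` may be
    ``None`` when two telomeric cuts fuse into a single junction).
    ``dups`` lists the families duplicated by the first step.
    """

    kind: OpKind
    cut1: Adjacency
    cut2: Adjacency
    new1: Adjacency
    new2: Adjacency | None = None
    dups: tuple[int, ...] = ()

    def __str__(self) -> str:
        parts = [self.kind.value, str(self.cut1), str(self.cut2),
                 str(self.new1), str(self.new2) if self.new2 else "()"]
        s = ";".join(parts)
        if self.dups:
            s += ";dup=" + ",".join(map(str, self.dups))
        return s


@dataclass
class Scenario:
    """An ordered, replayable list of rearrangement operations."""

    ops: list[RearrangementOp] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self):
        return iter(self.ops)

    def __str__(self) -> str:
        return "".join(str(op) + "\n" for op in self.ops)


# ---------------------------------------------------------------------------
# core DCJ
# ---------------------------------------------------------------------------

def _dcj_on_adjacency_set(g: Genome, cut1: Adjacency, cut2: Adjacency,
                          news: Sequence[Adjacency]) -> Genome:
    adjset = adjacencies(g)
    if cut1 == cut2:
        raise IdenticalCuts(f"cannot cut {cut1} twice")
    for cut in (cut1, cut2):
        if cut not in adjset:
            raise AdjacencyNotFound(f"adjacency {cut} not in genome")
    exposed = set(cut1.extremities()) | set(cut2.extremities())
    covered: set = set()
    for new in news:
        exts = set(new.extremities())
        if not exts <= exposed or exts & covered:
            raise InvalidRejoin(f"new adjacency {new} does not use exposed extremities")
        covered |= exts
    # uncovered exposed extremities become telomeres
    adjset.discard(cut1)
    adjset.discard(cut2)
    for new in news:
        adjset.add(new)
    for e in exposed - covered:
        adjset.add(adjacency_from_extremities(e, None))
    return genome_from_adjacencies(adjset)


def apply_dcj(g: Genome, op: RearrangementOp) -> Genome:
    """Apply a plain DCJ (or the reversal special case) given explicit
    cut and new adjacencies."""
    news = [op.new1] + ([op.new2] if op.new2 is not None else [])
    result = _dcj_on_adjacency_set(g, op.cut1, op.cut2, news)
    if op.kind is OpKind.REVERSAL:
        _check_reversal(g, result, op)
    return result


def _chromosome_index(g: Genome, adj: Adjacency) -> int:
    for i, chrom in enumerate(g.chromosomes):
        if adj in adjacencies(Genome((chrom,))):
            return i
    raise AdjacencyNotFound(str(adj))


def _check_reversal(before: Genome, after: Genome, op: RearrangementOp) -> None:
    if _chromosome_index(before, op.cut1) != _chromosome_index(before, op.cut2):
        raise CutsOnDifferentChromosomes(f"{op.cut1} / {op.cut2}")
    shapes = sorted((c.circular, len(c)) for c in before.chromosomes)
    if shapes != sorted((c.circular, len(c)) for c in after.chromosomes):
        raise InvalidRejoin("rejoin does not realize a reversal")


def make_dcj(g: Genome, cut1: Adjacency, cut2: Adjacency, new1: Adjacency,
             new2: Adjacency | None = None) -> RearrangementOp:
    return RearrangementOp(OpKind.DCJ, cut1, cut2, new1, new2)


def reversal_news(g: Genome, cut1: Adjacency, cut2: Adjacency) -> tuple[Adjacency, Adjacency]:
    """New adjacencies of the reversal cutting ``cut1`` and ``cut2``.

    For cuts (a b) and (c d) in chromosome order the reversal produces
    (a -c) and (-b d).
    """
    ci = _chromosome_index(g, cut1)
    if ci != _chromosome_index(g, cut2):
        raise CutsOnDifferentChromosomes(f"{cut1} / {cut2}")
    chrom = g.chromosomes[ci]
    p, q = sorted((_cut_positions(chrom, cut1), _cut_positions(chrom, cut2)))
    if p == q:
        raise IdenticalCuts(str(cut1))
    ms = chrom.markers
    # gap index i sits before ms[i]; p < q, so b = ms[p] and c = ms[q-1]
    # are always real markers while a and d may be telomere caps.
    a = ms[p - 1] if p > 0 else TELOMERE
    b = ms[p]
    c = ms[q - 1]
    d = ms[q] if q < len(ms) else TELOMERE
    return Adjacency(a, -c), Adjacency(-b, d)


def _cut_positions(chrom: Chromosome, adj: Adjacency) -> int:
    """Gap index (0..len) of an adjacency within a linear chromosome."""
    ms = chrom.markers
    if chrom.circular:
        raise CutsOnDifferentChromosomes("reversal on circular chromosome unsupported")
    for i in range(len(ms) + 1):
        left = ms[i - 1] if i > 0 else TELOMERE
        right = ms[i] if i < len(ms) else TELOMERE
        if Adjacency(left, right) == adj:
            return i
    raise AdjacencyNotFound(str(adj))


def make_reversal(g: Genome, cut1: Adjacency, cut2: Adjacency) -> RearrangementOp:
    n1, n2 = reversal_news(g, cut1, cut2)
    return RearrangementOp(OpKind.REVERSAL, cut1, cut2, n1, n2)


def apply_reversal(g: Genome, op: RearrangementOp) -> Genome:
    if not op.kind.is_reversal:
        raise InvalidRejoin(f"not a reversal op: {op.kind}")
    return apply_dcj(g, RearrangementOp(OpKind.REVERSAL, op.cut1, op.cut2, op.new1, op.new2))


def reverse_segment(g: Genome, chrom_index: int, start: int, end: int) -> Genome:
    """Reverse (and negate) markers ``start..end`` (1-based, inclusive) of
    a linear chromosome.  Sequence-level helper used by the reversal
    solver; equivalent to the corresponding DCJ."""
    chrom = g.chromosomes[chrom_index]
    ms = chrom.markers
    if not (1 <= start <= end <= len(ms)):
        raise IndexError(f"segment {start}..{end} out of range")
    new = ms[:start - 1] + tuple(-m for m in reversed(ms[start - 1:end])) + ms[end:]
    chroms = list(g.chromosomes)
    chroms[chrom_index] = Chromosome(new, chrom.circular)
    return Genome(tuple(chroms))


# ---------------------------------------------------------------------------
# breakpoint-duplication
# ---------------------------------------------------------------------------

def _insert_copy(g: Genome, cut: Adjacency, family: int) -> Genome:
    """First BD step: realize the post-insertion adjacency ``cut`` for
    ``family`` by inserting the missing copy next to the existing one."""
    counts = g.family_counts()
    if counts.get(family, 0) != 1:
        raise AlreadyDuplicated(f"family {family} is not single-copy")
    # the cut is (u v) with u, v the two copies of the family, same sign
    u, v = cut.left, cut.right
    if u is TELOMERE or v is TELOMERE or u.family != family or v.family != family:
        raise InvalidRejoin(f"cut {cut} is not a duplication pattern for family {family}")
    present = None
    for m in g.markers():
        if m.family == family:
            present = m
            break
    assert present is not None
    # which of u, v is already present (by copy label)?
    if present.copy == u.copy:
        anchor, newcopy, after = u, v, True
    elif present.copy == v.copy:
        anchor, newcopy, after = v, u, False
    else:  # pragma: no cover - copies are 0/1
        raise InvalidRejoin(f"cut {cut} names no existing copy of family {family}")
    chroms = []
    for chrom in g:
        out = []
        for m in chrom.markers:
            if m.family != family:
                out.append(m)
                continue
            # insert so that the written pair realizes the cut adjacency:
            # occurrence matching the anchor's sign gets the new copy in
            # the recorded order, a flipped occurrence gets it mirrored.
            ins = Marker(family, newcopy.copy, newcopy.sign)
            if m.sign == anchor.sign:
                out.extend([m, ins] if after else [ins, m])
            else:
                out.extend([-ins, m] if after else [m, -ins])
        chroms.append(Chromosome(tuple(out), chrom.circular))
    return Genome(tuple(chroms))


def apply_bd(g: Genome, op: RearrangementOp) -> Genome:
    """Apply a BD operation: insert the declared copies, then run the
    recorded DCJ/reversal second step."""
    if not op.kind.is_bd:
        raise InvalidRejoin(f"not a BD op: {op.kind}")
    mid = g
    for family in op.dups:
        if not _is_dup_pattern(op.cut1, family) and not _is_dup_pattern(op.cut2, family):
            raise InvalidRejoin(f"no duplication cut recorded for family {family}")
        cut = op.cut1 if _is_dup_pattern(op.cut1, family) else op.cut2
        mid = _insert_copy(mid, cut, family)
    second = RearrangementOp(
        OpKind.REVERSAL if op.kind.is_reversal else OpKind.DCJ,
        op.cut1, op.cut2, op.new1, op.new2)
    return apply_dcj(mid, second)


def _is_dup_pattern(adj: Adjacency, family: int) -> bool:
    u, v = adj.left, adj.right
    return (u is not TELOMERE and v is not TELOMERE
            and u.family == family and v.family == family
            and u.copy != v.copy and u.sign == v.sign)


def _cut_families_dup(adj: Adjacency, family: int) -> set[int]:
    return {family} if _is_dup_pattern(adj, family) else set()


def second_step(op: RearrangementOp) -> RearrangementOp:
    """The plain DCJ/reversal inside an operation (identity for non-BD)."""
    if not op.kind.is_bd:
        return op
    return RearrangementOp(
        OpKind.REVERSAL if op.kind.is_reversal else OpKind.DCJ,
        op.cut1, op.cut2, op.new1, op.new2)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def apply_op(g: Genome, op: RearrangementOp) -> Genome:
    if op.kind.is_bd:
        return apply_bd(g, op)
    return apply_dcj(g, op)


def apply_scenario(g: Genome, scenario: Scenario | Iterable[RearrangementOp]) -> Genome:
    current = g
    for k, op in enumerate(scenario):
        try:
            current = apply_op(current, op)
        except Exception as exc:  # noqa: BLE001 - wrap with step index
            raise ScenarioInvalidAtStep(k, exc) from exc
    return current


def lift_bd_scenario(ancestor: Genome, scenario: Scenario) -> tuple[Genome, Scenario]:
    """Turn a BD scenario from a non-duplicated ancestor into a plain
    scenario of the same length from a dedoubled genome D with D^R = ancestor.

    D is the ancestor with, for every family duplicated along the
    scenario, the second copy inserted next to the first so that the
    couple already forms the sorted adjacency produced by its BD step.
    The plain scenario consists of the DCJ/reversal second steps in the
    original order; cut adjacencies are remapped where a pending copy
    sits between the original markers.
    """
    d = ancestor
    # pending copies: family -> the inserted pair pattern, applied up front
    for op in scenario:
        for family in op.dups:
            cut = op.cut1 if _is_dup_pattern(op.cut1, family) else op.cut2
            d = _insert_copy(d, cut, family)

    plain_ops: list[RearrangementOp] = []
    state = d
    pending: set[int] = {f for op in scenario for f in op.dups}
    for k, op in enumerate(scenario):
        step = second_step(op)
        for family in op.dups:
            pending.discard(family)
        adjset = adjacencies(state)
        subs: dict[gm.Extremity, gm.Extremity] = {}
        cuts = []
        for cut in (step.cut1, step.cut2):
            if cut in adjset:
                cuts.append(cut)
                continue
            remapped = _remap_cut(cut, pending, adjset)
            cuts.append(remapped)
            # extremities changed copy label only; match leftovers by family
            orig = set(cut.extremities())
            new = set(remapped.extremities())
            for e in orig - new:
                (e2,) = [x for x in new - orig if x[0] == e[0]]
                subs[e] = e2
        news = [_substitute_extremities(n, subs)
                for n in (step.new1, step.new2) if n is not None]
        try:
            state = _dcj_on_adjacency_set(state, cuts[0], cuts[1], news)
        except Exception as exc:  # noqa: BLE001
            raise ScenarioInvalidAtStep(k, exc) from exc
        plain_ops.append(RearrangementOp(step.kind, cuts[0], cuts[1],
                                         news[0], news[1] if len(news) > 1 else None))
    return d, Scenario(plain_ops)


def _remap_cut(cut: Adjacency, pending: set[int],
               adjset: set[Adjacency]) -> Adjacency:
    """Replace markers of a cut by their pending partner copies where the
    partner was inserted between the cut's markers in the lifted genome."""
    candidates = []
    for swap_left in (False, True):
        for swap_right in (False, True):
            if not (swap_left or swap_right):
                continue
            l, r = cut.left, cut.right
            if swap_left:
                if l is TELOMERE or l.family not in pending:
                    continue
                l = l.with_copy(1 - l.copy)
            if swap_right:
                if r is TELOMERE or r.family not in pending:
                    continue
                r = r.with_copy(1 - r.copy)
            candidates.append(Adjacency(l, r))
    for cand in candidates:
        if cand in adjset:
            return cand
    raise AdjacencyNotFound(f"cannot remap cut {cut}")


def _substitute_extremities(adj: Adjacency,
                            subs: dict[gm.Extremity, gm.Extremity]) -> Adjacency:
    if not subs:
        return adj
    l, r = adj.left, adj.right
    if l is not TELOMERE:
        e = gm.right_extremity(l)
        if e in subs:
            l = gm.marker_as_left(subs[e])
    if r is not TELOMERE:
        e = gm.left_extremity(r)
        if e in subs:
            r = gm.marker_as_right(subs[e])
    return Adjacency(l, r)


# ---------------------------------------------------------------------------
# scenario text format
# ---------------------------------------------------------------------------

def _parse_adjacency(text: str) -> Adjacency | None:
    text = text.strip()
    if text in ("()", ""):
        return None
    if not (text.startswith("(") and text.endswith(")")):
        raise ParseError(f"bad adjacency {text!r}")
    l, _, r = text[1:-1].partition(",")

    def side(tok):
        tok = tok.strip()
        return TELOMERE if tok == "$" else gm._parse_marker(tok)

    return Adjacency(side(l), side(r))


def parse_scenario(text: str) -> Scenario:
    ops = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split(";")]
        if len(fields) < 5:
            raise ParseError(f"line {lineno}: expected at least 5 ';'-separated fields")
        try:
            kind = OpKind(fields[0])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: unknown op kind {fields[0]!r}") from exc
        dups: tuple[int, ...] = ()
        if len(fields) > 5 and fields[5]:
            if not fields[5].startswith("dup="):
                raise ParseError(f"line {lineno}: expected dup= field")
            dups = tuple(int(x) for x in fields[5][4:].split(","))
        cut1, cut2 = _parse_adjacency(fields[1]), _parse_adjacency(fields[2])
        new1, new2 = _parse_adjacency(fields[3]), _parse_adjacency(fields[4])
        if cut1 is None or cut2 is None or new1 is None:
            raise ParseError(f"line {lineno}: cuts and first new adjacency are required")
        ops.append(RearrangementOp(kind, cut1, cut2, new1, new2, dups))
    return Scenario(ops)


def write_scenario(s: Scenario) -> str:
    return str(s)
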