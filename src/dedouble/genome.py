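"""Genomes with signed, copy-labelled markers.

A genome is a collection of linear or circular chromosomes over signed
integer markers.  A marker family may be present once or twice; the two
copies of a duplicated family (its *paralogs*) are distinguished by a
copy label, written ``x`` and ``x'`` (the *bar* copy).  The copy labels
are bookkeeping only: every quantity computed downstream is invariant
under swapping the two labels of any family.

Linear chromosomes carry implicit telomere caps at both ends.  An
adjacency is a pair of consecutive markers; because a chromosome can be
read in either direction, ``(x y)`` and ``(-y -x)`` denote the same
adjacency.

The module also implements the two reductions used before solving:

* ``reduce_dedoubled`` collapses every sorted couple ``x x'`` to a
  single marker, producing the non-duplicated ancestor;
* ``totalize`` replaces every maximal run of non-duplicated markers by
  an already-sorted couple, turning an arbitrary duplicated genome into
  a totally duplicated one without changing the dedoubling distance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .errors import (
    MissingKeyError,
    NotDedoubledError,
    ParseError,
)

PLAIN = 0
BAR = 1

HEAD = "h"
TAIL = "t"

#: extremity of a marker copy: (family, copy, end)
Extremity = tuple[int, int, str]


@dataclass(frozen=True, order=True)
class Marker:
    """A signed occurrence of a marker family.

    ``copy`` is PLAIN (0) or BAR (1); ``sign`` is +1 or -1.  Negation
    flips the sign only: ``-(-x) == x``.
    """

    family: int
    copy: int = PLAIN
    sign: int = 1

    def __neg__(self) -> "Marker":
        return Marker(self.family, self.copy, -self.sign)

    def with_copy(self, copy: int) -> "Marker":
        return Marker(self.family, copy, self.sign)

    def __str__(self) -> str:
        return ("-" if self.sign < 0 else "") + str(self.family) + ("'" if self.copy == BAR else "")


class _Telomere:
    """Singleton cap of a linear chromosome, printed as ``$``."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "$"


TELOMERE = _Telomere()


def _marker_key(m) -> tuple:
    """Sort key for adjacency canonicalization; telomere sorts last."""
    if m is TELOMERE:
        return (1, 0, 0, 0)
    return (0, m.family, m.copy, 0 if m.sign > 0 else 1)


def right_extremity(m: Marker) -> Extremity:
    """Extremity at the right (reading) end of a written marker."""
    return (m.family, m.copy, HEAD if m.sign > 0 else TAIL)


def left_extremity(m: Marker) -> Extremity:
    return (m.family, m.copy, TAIL if m.sign > 0 else HEAD)


def marker_as_left(e: Extremity) -> Marker:
    """Marker written on the left of a junction whose right end is ``e``."""
    f, c, end = e
    return Marker(f, c, 1 if end == HEAD else -1)


def marker_as_right(e: Extremity) -> Marker:
    """Marker written on the right of a junction whose left end is ``e``."""
    f, c, end = e
    return Marker(f, c, 1 if end == TAIL else -1)


@dataclass(frozen=True)
class Adjacency:
    """An unordered pair of consecutive markers (or marker and telomere).

    The constructor canonicalizes between the two equivalent writings
    ``(x y)`` and ``(-y -x)``: the writing whose left marker has the
    smaller ``(family, copy, sign)`` triple is kept, and a telomere is
    always written on the right.
    """

    left: object
    right: object

    def __post_init__(self):
        l, r = self.left, self.right
        if l is TELOMERE and r is TELOMERE:
            raise ValueError("adjacency of two telomere caps")
        fl, fr = (-r if r is not TELOMERE else TELOMERE,
                  -l if l is not TELOMERE else TELOMERE)
        if (_marker_key(fl), _marker_key(fr)) < (_marker_key(l), _marker_key(r)):
            object.__setattr__(self, "left", fl)
            object.__setattr__(self, "right", fr)

    @property
    def telomeric(self) -> bool:
        return self.left is TELOMERE or self.right is TELOMERE

    def extremities(self) -> tuple[Extremity, ...]:
        """The one or two marker extremities glued at this junction."""
        out = []
        if self.left is not TELOMERE:
            out.append(right_extremity(self.left))
        if self.right is not TELOMERE:
            out.append(left_extremity(self.right))
        return tuple(out)

    def families(self) -> set[int]:
        out = set()
        for m in (self.left, self.right):
            if m is not TELOMERE:
                out.add(m.family)
        return out

    def sort_key(self) -> tuple:
        return (_marker_key(self.left), _marker_key(self.right))

    def __str__(self) -> str:
        l = "$" if self.left is TELOMERE else str(self.left)
        r = "$" if self.right is TELOMERE else str(self.right)
        return f"({l},{r})"


def adjacency(left, right) -> Adjacency:
    return Adjacency(left, right)


def adjacency_from_extremities(e1: Extremity | None, e2: Extremity | None) -> Adjacency:
    """Adjacency gluing two extremities; one may be ``None`` (telomeric)."""
    if e1 is None and e2 is None:
        raise ValueError("empty adjacency")
    if e1 is None:
        e1, e2 = e2, None
    if e2 is None:
        return Adjacency(marker_as_left(e1), TELOMERE)
    return Adjacency(marker_as_left(e1), marker_as_right(e2))


@dataclass(frozen=True)
class Chromosome:
    markers: tuple[Marker, ...]
    circular: bool = False

    def __post_init__(self):
        if not self.markers:
            raise ValueError("empty chromosome")

    def __len__(self) -> int:
        return len(self.markers)

    def reversed(self) -> "Chromosome":
        return Chromosome(tuple(-m for m in reversed(self.markers)), self.circular)


@dataclass(frozen=True)
class Genome:
    chromosomes: tuple[Chromosome, ...]

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)

    def markers(self) -> Iterator[Marker]:
        for chrom in self.chromosomes:
            yield from chrom.markers

    def family_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for m in self.markers():
            counts[m.family] = counts.get(m.family, 0) + 1
        return counts

    def duplicated_families(self) -> set[int]:
        return {f for f, c in self.family_counts().items() if c == 2}

    @property
    def unichromosomal_linear(self) -> bool:
        return len(self.chromosomes) == 1 and not self.chromosomes[0].circular


def genome(*chromosome_specs) -> Genome:
    """Convenience constructor used heavily in tests: ``genome([...], circular([...]))``."""
    chroms = []
    for spec in chromosome_specs:
        if isinstance(spec, Chromosome):
            chroms.append(spec)
        else:
            chroms.append(Chromosome(tuple(spec), circular=False))
    return Genome(tuple(chroms))


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

_MARKER_RE = re.compile(r"^(-?)(\d+)('?)$")


def _parse_marker(token: str) -> Marker:
    m = _MARKER_RE.match(token)
    if not m:
        raise ParseError(f"bad marker token {token!r}")
    family = int(m.group(2))
    if family < 1:
        raise ParseError(f"marker family must be >= 1, got {token!r}")
    return Marker(family, BAR if m.group(3) else PLAIN, -1 if m.group(1) else 1)


def parse_genome(text: str) -> Genome:
    """Parse the plain-text genome format.

    One chromosome per line: ``L`` (linear) or ``C`` (circular) followed
    by whitespace-separated markers, e.g. ``L 1 -2 2' 1'``.  ``#``
    starts a comment; blank lines are ignored.  Copy labels are
    canonicalized so that the first occurrence of each family in reading
    order is the plain copy.
    """
    chroms: list[Chromosome] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] not in ("L", "C"):
            raise ParseError(f"line {lineno}: chromosome must start with 'L' or 'C'")
        if len(parts) < 2:
            raise ParseError(f"line {lineno}: empty chromosome")
        markers = tuple(_parse_marker(tok) for tok in parts[1:])
        chroms.append(Chromosome(markers, circular=parts[0] == "C"))
    if not chroms:
        raise ParseError("no chromosomes found")
    g = Genome(tuple(chroms))
    _validate_copies(g)
    return canonicalize_copies(g)


def _validate_copies(g: Genome) -> None:
    seen: dict[tuple[int, int], int] = {}
    for m in g.markers():
        key = (m.family, m.copy)
        seen[key] = seen.get(key, 0) + 1
    families: dict[int, int] = {}
    for (f, c), n in seen.items():
        if n > 1:
            label = "bar" if c == BAR else "plain"
            raise ParseError(f"family {f}: {label} copy appears {n} times")
        families[f] = families.get(f, 0) + n
    for f, n in families.items():
        if n > 2:
            raise ParseError(f"family {f} appears {n} times (at most 2 allowed)")


def canonicalize_copies(g: Genome) -> Genome:
    """Relabel copies so the first occurrence of each family is plain."""
    swap: set[int] = set()
    seen: set[int] = set()
    for m in g.markers():
        if m.family not in seen:
            seen.add(m.family)
            if m.copy == BAR:
                swap.add(m.family)
    if not swap:
        return g
    return swap_copy_labels(g, swap)


def swap_copy_labels(g: Genome, families: Iterable[int]) -> Genome:
    fams = set(families)
    chroms = []
    for chrom in g:
        chroms.append(Chromosome(
            tuple(m.with_copy(1 - m.copy) if m.family in fams else m for m in chrom.markers),
            chrom.circular))
    return Genome(tuple(chroms))


def write_genome(g: Genome) -> str:
    lines = []
    for chrom in g:
        prefix = "C" if chrom.circular else "L"
        lines.append(prefix + " " + " ".join(str(m) for m in chrom.markers))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# adjacencies
# ---------------------------------------------------------------------------

def adjacencies(g: Genome) -> set[Adjacency]:
    """All adjacencies of the genome.

    A linear chromosome of length ``k`` yields ``k + 1`` adjacencies
    (two of them telomeric); a circular chromosome of length ``k``
    yields ``k``.
    """
    out: set[Adjacency] = set()
    for chrom in g:
        ms = chrom.markers
        if chrom.circular:
            for i in range(len(ms)):
                out.add(Adjacency(ms[i], ms[(i + 1) % len(ms)]))
        else:
            out.add(Adjacency(TELOMERE, ms[0]))
            for i in range(len(ms) - 1):
                out.add(Adjacency(ms[i], ms[i + 1]))
            out.add(Adjacency(ms[-1], TELOMERE))
    return out


def extremity_map(g: Genome) -> dict[Extremity, Adjacency]:
    """Map each marker extremity to the unique adjacency housing it."""
    out: dict[Extremity, Adjacency] = {}
    for adj in adjacencies(g):
        for e in adj.extremities():
            out[e] = adj
    return out


def genome_from_adjacencies(adjs: Iterable[Adjacency]) -> Genome:
    """Rebuild chromosome sequences from an adjacency set.

    Inverse of :func:`adjacencies` up to chromosome order and reading
    direction.  Every marker extremity must occur exactly once.
    """
    adjset = set(adjs)
    ext_to_adj: dict[Extremity, Adjacency] = {}
    for adj in adjset:
        for e in adj.extremities():
            if e in ext_to_adj:
                raise ValueError(f"extremity {e} occurs twice")
            ext_to_adj[e] = adj

    used: set[Adjacency] = set()
    chroms: list[Chromosome] = []

    # linear chromosomes: walk from each unused telomeric adjacency.  The
    # canonical telomeric form is (m, $); read with the cap on the left the
    # chromosome starts with -m.
    telomeric = sorted((a for a in adjset if a.telomeric), key=Adjacency.sort_key)
    for start in telomeric:
        if start in used:
            continue
        used.add(start)
        seq = [-start.left]
        while True:
            e = right_extremity(seq[-1])
            junction = ext_to_adj.get(e)
            if junction is None:
                raise ValueError(f"dangling extremity {e}")
            used.add(junction)
            if junction.telomeric:
                break
            exts = junction.extremities()
            partner = exts[0] if exts[1] == e else exts[1]
            seq.append(marker_as_right(partner))
        chroms.append(Chromosome(tuple(seq), circular=False))

    # remaining adjacencies close into circular chromosomes
    remaining = sorted((a for a in adjset if a not in used), key=Adjacency.sort_key)
    for start in remaining:
        if start in used:
            continue
        used.add(start)
        seq = [start.right]
        while True:
            e = right_extremity(seq[-1])
            junction = ext_to_adj[e]
            if junction is start:
                break
            if junction in used:
                raise ValueError("inconsistent adjacency set")
            used.add(junction)
            exts = junction.extremities()
            partner = exts[0] if exts[1] == e else exts[1]
            seq.append(marker_as_right(partner))
        chroms.append(Chromosome(tuple(seq), circular=True))

    return Genome(tuple(chroms))


# ---------------------------------------------------------------------------
# classification, reduction, totalization
# ---------------------------------------------------------------------------

def dedoubled_adjacency_forms(family: int) -> tuple[Adjacency, Adjacency]:
    """The two admissible sorted forms of a couple: ``(x x')`` and ``(x' x)``."""
    x = Marker(family, PLAIN, 1)
    xb = Marker(family, BAR, 1)
    return (Adjacency(x, xb), Adjacency(xb, x))


def classify(g: Genome) -> tuple[str, bool]:
    """Duplication status and dedoubled flag.

    Returns ``(kind, is_dedoubled)`` with kind one of ``non_duplicated``,
    ``duplicated``, ``totally_duplicated``.  The genome is dedoubled when
    every duplicated family ``x`` has adjacency ``(x x')`` or ``(x' x)``
    — equivalently ``(-x' -x)`` or ``(-x -x')``.  The inverted-adjacent
    form ``(x -x')`` is *not* dedoubled.
    """
    counts = g.family_counts()
    dup = {f for f, c in counts.items() if c == 2}
    if not dup:
        kind = "non_duplicated"
    elif len(dup) == len(counts):
        kind = "totally_duplicated"
    else:
        kind = "duplicated"
    adjset = adjacencies(g)
    dedoubled = all(
        forms[0] in adjset or forms[1] in adjset
        for forms in map(dedoubled_adjacency_forms, dup)
    )
    return kind, dedoubled


def is_dedoubled(g: Genome) -> bool:
    return classify(g)[1]


def reduce_dedoubled(g: Genome) -> Genome:
    """Collapse every sorted couple to a single marker (the reduction G^R).

    The collapsed marker carries the common orientation of the pair:
    ``(x x')`` and ``(x' x)`` reduce to ``x``; ``(-x' -x)`` reduces to
    ``-x``.  Raises :class:`NotDedoubledError` if some duplicated couple
    is not in sorted form.
    """
    dup = g.duplicated_families()
    chroms: list[Chromosome] = []
    for chrom in g:
        ms = list(chrom.markers)
        if chrom.circular and ms and any(m.family in dup for m in ms):
            # rotate so that position 0 starts a couple pair (never in the middle of one)
            for shift in range(len(ms)):
                first = ms[shift]
                prev = ms[shift - 1]
                if first.family in dup and prev.family == first.family:
                    continue  # would split the pair prev,first
                ms = ms[shift:] + ms[:shift]
                break
        out: list[Marker] = []
        i = 0
        while i < len(ms):
            m = ms[i]
            if m.family not in dup:
                out.append(m)
                i += 1
                continue
            if i + 1 < len(ms):
                nxt = ms[i + 1]
            elif chrom.circular:
                nxt = ms[0]
            else:
                raise NotDedoubledError(f"family {m.family} not in sorted form")
            if nxt.family == m.family and nxt.copy != m.copy and nxt.sign == m.sign:
                out.append(Marker(m.family, PLAIN, m.sign))
                i += 2
            else:
                raise NotDedoubledError(f"family {m.family} not in sorted form")
        if not out:
            raise NotDedoubledError("chromosome vanished during reduction")
        chroms.append(Chromosome(tuple(out), chrom.circular))
    return Genome(tuple(chroms))


#: maps an introduced couple's family to the original run it replaced
RunMap = dict


def totalize(g: Genome) -> tuple[Genome, RunMap]:
    """Replace each maximal run of non-duplicated markers by a sorted couple.

    A run read left-to-right beginning with signed marker ``s.x`` becomes
    the pair ``s.x s.x'`` — already in dedoubled form, so the couple
    contributes one independent self-loop to the adjacency graph and
    adds nothing to the dedoubling distance.  The returned run map lets
    :func:`expand_ancestor` restore the original markers afterwards.
    """
    dup = g.duplicated_families()
    runmap: RunMap = {}
    chroms: list[Chromosome] = []
    for chrom in g:
        ms = list(chrom.markers)
        if chrom.circular and any(m.family in dup for m in ms):
            for shift in range(len(ms)):
                if ms[shift].family in dup:
                    ms = ms[shift:] + ms[:shift]
                    break
        out: list[Marker] = []
        run: list[Marker] = []

        def flush():
            if not run:
                return
            head = run[0]
            runmap[head.family] = tuple(run)
            out.append(head)
            out.append(head.with_copy(BAR))
            run.clear()

        for m in ms:
            if m.family in dup:
                flush()
                out.append(m)
            else:
                run.append(m)
        flush()
        chroms.append(Chromosome(tuple(out), chrom.circular))
    return Genome(tuple(chroms)), runmap


def expand_ancestor(g: Genome, runmap: Mapping[int, tuple[Marker, ...]]) -> Genome:
    """Inverse of :func:`totalize` on a reduced genome.

    Each run-map key must occur exactly once as a non-duplicated marker;
    it is replaced by its stored run, reversed-and-negated when the key
    appears with flipped sign.
    """
    keys = set(runmap)
    seen: set[int] = set()
    chroms: list[Chromosome] = []
    for chrom in g:
        out: list[Marker] = []
        for m in chrom.markers:
            if m.family not in keys:
                out.append(m)
                continue
            if m.family in seen:
                raise MissingKeyError(f"run key {m.family} occurs more than once")
            seen.add(m.family)
            run = runmap[m.family]
            head = run[0]
            if m.sign == head.sign:
                out.extend(run)
            else:
                out.extend(-r for r in reversed(run))
        chroms.append(Chromosome(tuple(out), chrom.circular))
    missing = keys - seen
    if missing:
        raise MissingKeyError(f"run keys absent from genome: {sorted(missing)}")
    return Genome(tuple(chroms))


# ---------------------------------------------------------------------------
# canonical forms / equivalence
# ---------------------------------------------------------------------------

def _chrom_tuple(chrom: Chromosome) -> tuple:
    return tuple((m.family, m.copy, m.sign) for m in chrom.markers)


def _seq_canonical(seq: tuple, circular: bool) -> tuple:
    rev = tuple((f, c, -s) for (f, c, s) in reversed(seq))
    if not circular:
        return ("L",) + (seq if seq <= rev else rev)
    best = None
    for base in (seq, rev):
        for i in range(len(base)):
            rot = base[i:] + base[:i]
            if best is None or rot < best:
                best = rot
    return ("C",) + best


def _chrom_canonical(chrom: Chromosome) -> tuple:
    return _seq_canonical(_chrom_tuple(chrom), chrom.circular)


def canonical_form(g: Genome, max_swap_families: int = 16) -> tuple:
    """A hashable form invariant under chromosome order, reading
    direction, circular rotation, and copy-label swaps.

    The copy-label minimization enumerates swap subsets of the
    duplicated families, so it is restricted to genomes with at most
    ``max_swap_families`` duplicated families.
    """
    dup = sorted(g.duplicated_families())
    if len(dup) > max_swap_families:
        raise ValueError(f"too many duplicated families for canonicalization: {len(dup)}")
    chroms = [(_chrom_tuple(c), c.circular) for c in g.chromosomes]
    best = None
    for mask in range(1 << len(dup)):
        fams = frozenset(f for i, f in enumerate(dup) if mask >> i & 1)
        form = tuple(sorted(
            _seq_canonical(
                tuple((f, 1 - c, s) if f in fams else (f, c, s) for (f, c, s) in seq)
                if fams else seq,
                circ)
            for seq, circ in chroms))
        if best is None or form < best:
            best = form
    return best


def genomes_equivalent(a: Genome, b: Genome) -> bool:
    """Equality up to chromosome order, reading direction, rotation and
    copy-label swap."""
    return canonical_form(a) == canonical_form(b)
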