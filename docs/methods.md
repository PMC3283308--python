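# Methods

## Model

A genome is a multiset of chromosomes over signed integer markers; a
family occurs once or twice, the two copies of a *couple* being
distinguished by an arbitrary bar label (`x` / `x'`). Linear
chromosomes carry implicit telomere caps; an adjacency is an unordered
pair of consecutive marker extremities, so `(x y) ≡ (−y −x)`, and the
canonical written form puts the smaller `(family, copy, sign)` triple
on the left with telomeres last. All quantities computed here are
invariant under swapping the two labels of any family, under chromosome
order, reading direction and circular rotation; `canonical_form`
realizes that symmetry group and backs both genome equality in tests
and state deduplication in the search oracles.

A *DCJ* cuts two different adjacencies and re-glues the exposed
extremities crosswise; a *reversal* is the DCJ on one chromosome whose
rejoin inverts the intervening segment. A *breakpoint-duplication*
(BD) operation first inserts a copy of one marker per designated
breakpoint — the copy flanks the cut, producing the pattern `a a' | b`
— and then applies the DCJ/reversal on the modified adjacencies. With
two duplicating breakpoints (2-BD) both cut adjacencies are such
patterns. Operations are stored with their post-insertion cut
adjacencies and explicit new adjacencies, which makes scenarios
deterministic and bit-exactly replayable; the scenario text format is
one operation per line, `KIND;cut1;cut2;new1;new2[;dup=families]`.

## The distance actually computed

The dedoubling distance implemented throughout is

> d(G) = min over dedoubled genomes D of the DCJ (resp. reversal)
> distance between D and G,

where *dedoubled* means every couple forms an adjacency `(x x')` or
`(x' x)`. Collapsing those pairs in the optimal D yields the reported
ancestor. This is deliberately not the same number as "count every
operation of a BD scenario from a non-duplicated genome": under that
literal count a genome whose couples are all already sorted would still
cost at least ⌈n/2⌉ operations merely to create its n couples, and no
totalization could preserve the count because introducing couples
raises that floor. Duplications that survive in sorted form are
treated as free — the BD event that produced them needs no subsequent
rearrangement of its own. The test suite keeps both readings honest: a
brute-force BD-scenario oracle (`bd_dcj_oracle`, BFS over inverse BD
operations) verifies that the literal count always dominates the
implemented distance, while the dedoubled-target oracle (`bfs_oracle`)
verifies the implemented formulas exactly.

## Graphs and formulas

The dedoubled adjacency graph A(G) of a totally duplicated genome has
the adjacencies as vertices and, per couple x, edge `E_head(x)` joining
the adjacency housing head(plain) to the one housing tail(bar) and
edge `E_tail(x)` joining tail(plain) to head(bar). This is the unique
head/tail pairing under which precisely the sorted forms produce
self-loops, which the distance theory requires. Degrees are 1
(telomeric) or 2, so components are paths (two per linear chromosome)
and cycles. With n couples and C_i the maximum number of pairwise
couple-disjoint non-duplicated cycles:

* unrestricted DCJ: `d = n − C_i`;
* single linear chromosome to single linear chromosome:
  `d = n − C + 2m`, with C the total cycle count and `m = C − C_i`
  the minimum number of cycles to merge into the path to make it
  *valid* (containing every couple);
* reversals on an oriented genome: `d = n − C + 2m` again.

C_i is a maximum independent set on the conflict graph of the
non-duplicated cycles. The exact solver is a branch-and-bound on the
maximum-degree node with an isolated-node fast path, deterministic
tie-breaks, and a default gate of 25 nodes (`SizeLimitExceeded`
beyond; desk-scale genomes give single-digit node counts). The greedy
alternative repeatedly takes a minimum-degree node (ties: smallest
couple set, then index); its ≥ ½-of-optimum behaviour is enforced
empirically against the exact solver over hundreds of seeded instances
rather than proven, since we do not reproduce the published
2-approximation construction.

## Sorting strategies

**General DCJ sorter.** Re-derived each step from the current graph:
while some selected cycle still has k ≥ 2 couples, one DCJ cuts the two
endpoint adjacencies of one of its couple-edges and rejoins them into
the couple's sorted adjacency, splitting off a self-loop; when only
self-loops remain selected, each uncovered couple is sorted by the same
resolution applied to its head edge (whose endpoints never touch
selected cycles). Each step is verified at run time to decrease the
exact distance by one; a violation raises `InternalError` rather than
emitting a wrong scenario.

**Single-linear DCJ sorter.** The merge phase brings every non-selected
cycle into the path and the resolution phase sorts couples, but rejoin
choices interact with chromosome structure: sorting a couple whose
copies have equal signs excises a transient circular chromosome that a
later resolution must reabsorb. Rather than fix one global rejoin
policy, the sorter searches depth-first over the constructive moves —
resolutions through either edge of any unsorted couple, and merges
pairing a cycle adjacency with each path adjacency — bounded by the
exact budget `n − C + 2m`, with memoization on canonicalized states,
successors ordered to prefer chromosome-merging and reversal-type
moves, and pruning by the unrestricted DCJ lower bound and the circular
chromosome count. The first dive almost always succeeds; the bound was
met on every instance exercised (hundreds of seeds, n ≤ 8), and a miss
would raise `InternalError`, never silently emit a longer scenario.

**Reversal sorter.** Defined for oriented genomes only; unoriented
inputs raise `UnorientedGenomeError` (the orientation surcharge is out
of scope here). The overlap graph has one vertex per couple with the
interval between its copies; edges join *properly crossing* intervals
— intersecting with neither containing the other. The containment-free
reading is forced: including containments would merge two of the
published genome's four overlap components. A vertex is oriented when its copies
have opposite signs, and sorted vertices (already dedoubled, hence
equal-signed and isolated) are excluded from component classification
and from scores — otherwise a genome one reversal away from sorted
would classify as unoriented. Phase 1 applies merging reversals (one
cut in a non-selected cycle, one in the path; the candidate pair is
the cycle's smallest adjacency against the span-minimizing path
adjacency, falling back to other pairs); phase 2 repeatedly applies
`rho` (reverse `i+1..j`) or `rho_bar` (reverse `i..j−1`) of a
maximum-score oriented vertex, ties to the smallest family, preferring
`rho`. Whether the preferred variant extracts a cycle is not assumed:
every candidate step is accepted only if the genome stays oriented and
the exact distance drops by one, with exhaustive fallback over oriented
vertices and variants; the theory guarantees such a step exists and no
tested instance ever needed the guard to fail.

The overlap-graph effect of a sorting reversal is local
complementation: complement the closed neighbourhood, flip its
orientations, isolate newly sorted vertices. Both this transform and a
generic interval-arithmetic transform for arbitrary reversals are
implemented genome-free and checked against full rebuilds after every
emitted reversal.

## Totalization and the ancestor

A partially duplicated genome is reduced by replacing each maximal run
of non-duplicated markers, beginning with signed marker `s·x`, by the
already-sorted pair `s·x s·x'`. The placement adds one couple and one
independent self-loop, hence zero distance, which the brute-force
oracles confirm on exhaustively enumerated tiny instances; the run map
is invertible, and `expand_ancestor(reduce_dedoubled(end), runmap)`
restores the original markers in the reconstructed ancestor (reversed
and negated where the collapsed marker ends up flipped).

## Synthetic data and oracles

The simulator evolves a random non-duplicated ancestor (families
`1..n`, random order and signs, optionally several or circular
chromosomes) through k operations drawn as 40% 1-BD, 30% 2-BD, 30%
plain — defaults chosen to exercise every operation kind, as no
generative mixture is prescribed by the model — with the reversal
variant drawing only (BD-)reversals and an `oriented_only` filter that
redraws until the totalized derived genome is oriented. The derived
genome's distance is bounded by k by construction, which the solvers
must respect; with k = 0 it is zero.

What the generator emulates is the combinatorial mechanism only:
markers are abstract oriented segments, every breakpoint is usable,
copies are exact. Real data additionally involve marker inference from
alignments, more than two copies per family, divergence between
copies, and rates that vary along the chromosome; passing tests say
nothing about those steps.

The exact-distance oracles do bidirectional BFS between the input and
the enumerated set of dedoubled genomes over the same marker content
(DCJ and reversal successor relations are symmetric), over states
canonicalized by the full symmetry group; a plain forward BFS
cross-checks the bidirectional implementation on small cases. Default
gate: 3 couples (6 markers). Oracle agreement is tested exhaustively
for two couples and on 100 seeded three-couple genomes per model.

## Problem sizes used in the tests

Scenario soundness runs 200 seeded genomes per model at n ≤ 7;
the simulation bound 500 evolutions at k ≤ 6; the greedy ratio 500
instances at n ≤ 10; oracle equivalence all two-couple genomes up to
symmetry plus 100 seeded three-couple genomes per model. These sizes
keep the brute-force references exact while covering every code path;
the solvers themselves handle larger instances (the conflict graphs
stay tiny) and the published 26-marker genome (13 couples) end to end.

## Known limitations

* Unoriented genomes under the reversal model are rejected, not
  costed; the orientation term is future work in the source theory.
* The exact MIS gate defaults to 25 conflict nodes; beyond that choose
  `greedy` or raise the limit explicitly.
* The single-linear DCJ sorter's search is exponential in the worst
  case in principle; in practice the constructive ordering makes it
  effectively linear in the scenario length on everything tested.
* Reported greedy-method scenarios may be shorter than the greedy
  formula suggests (greedy selections are re-derived per step); the
  reported distance for greedy runs is the actual scenario length.
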