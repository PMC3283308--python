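# dedouble

Minimum rearrangement scenarios for genomes whose duplicated segments
were left behind by *breakpoint-duplication* rearrangements, and
reconstruction of the non-duplicated ancestral genome.

## The problem

Comparative studies in mammals and in the *Drosophila* species group
repeatedly find duplicated segments sitting at the breakpoints of
evolutionary rearrangements: a rearrangement cuts the chromosome and
the repair leaves a copy of a flanking segment on both sides of the
break, often inverted. `dedouble` models this process combinatorially.
A genome is a set of linear or circular chromosomes over signed integer
markers, with at most two copies per marker family (the copies `x` and
`x'` of a *couple* are interchangeable labels). A
*breakpoint-duplication DCJ* (BD-DCJ) first copies a marker next to its
original at one or both breakpoints and then applies an ordinary
double-cut-and-join; a *BD-reversal* is the same with a reversal as
second step.

The **genome dedoubling problem** asks, given a present-day duplicated
genome G, for a shortest rearrangement history from a non-duplicated
ancestor under this model. Equivalently (and this is how the package
computes it), it asks for a *dedoubled* genome D — one in which every
couple forms an adjacency `(x x')` or `(x' x)` — minimizing the
DCJ/reversal distance to G; collapsing each couple of D to a single
marker yields the ancestor.

## The method

Everything reduces to a totally duplicated genome (runs of
non-duplicated markers are replaced by ready-sorted couples, reversibly)
and is then read off one graph:

* the **dedoubled adjacency graph** A(G) has one vertex per adjacency
  of G and two edges per couple, pairing head(`x`) with tail(`x'`) and
  tail(`x`) with head(`x'`). Its components are paths and cycles, and a
  couple is sorted exactly when one of its edges is a self-loop.
* With `n` couples and `C_i` the maximum number of pairwise
  *independent* (couple-disjoint) non-duplicated cycles, the DCJ
  dedoubling distance is `d_DCJ(G) = n − C_i`. Choosing the cycle set
  is an NP-hard (2-approximable) maximum-independent-set subproblem;
  the package ships an exact branch-and-bound (default) and a
  deterministic greedy.
* If both G and the target must be a single linear chromosome,
  `d = n − C + 2m`, where `C` counts all cycles and `m = C − C_i` is
  the number of cycles that must be *merged* into the unique path to
  make it contain every couple.
* For **reversals** on an *oriented* genome (every component of the
  interval overlap graph of the couples contains a couple whose copies
  have opposite signs), the same formula `d_rev(G) = n − C + 2m` holds,
  and a quadratic-time sorter produces an explicit scenario: merging
  reversals first, then maximum-score sorting reversals driven by
  local complementation, Hannenhalli–Pevzner style.

Scenarios are explicit, replayable operation lists; every emitted step
provably decreases the remaining exact distance by one (checked at run
time).

## Worked example

A 16-marker chromosome with eight couples, of which only two
independent cycles can be selected (`C_i = 2`):

```
$ cat worked.gdd
L 1 2 2' 1' 3 4 4' 3' 5 6 5' 6' 7 8 7' 8'

$ gdd distance worked.gdd --model dcj
model: dcj
method: exact
n: 8
C: 4
C_i: 2
m: None
distance: 6

$ gdd distance worked.gdd --model dcj-linear
model: dcj_linear
method: exact
n: 8
C: 4
C_i: 2
m: 2
distance: 8
```

Unrestricted DCJ needs `8 − 2 = 6` operations; insisting that the
result stay one linear chromosome costs two extra operations
(`8 − 4 + 2·2 = 8`), one per cycle that has to be merged back into the
path. Sorting a partially duplicated genome totalizes it first and
reconstructs the ancestor:

```
$ cat partial.gdd
L 1 5 6 2 2' 1'

$ gdd sort partial.gdd --model dcj-linear -o scenario.txt --ancestor ancestor.gdd
distance: 2 (dcj_linear, exact)
ancestor: L -1 5 6 2

$ cat scenario.txt
DCJ;(1,5);(-1,$);(-1,5);(1,$)
DCJ;(1,$);(-1',-2');(1,1');(2',$)
```

The run `5 6` was folded into one couple for solving and restored in
the ancestor; the two recorded operations replay exactly (cut
adjacencies, then new adjacencies; `$` is a telomere).

The library mirrors the CLI: `parse_genome`, `totalize`,
`build_adjacency_graph`, `max_independent_cycles`, `dcj_distance`,
`dcj_sort_linear`, `build_overlap_graph`, `reversal_sort`,
`reduce_dedoubled`, `expand_ancestor`, plus seeded simulators
(`random_ancestor`, `random_bd_evolution`) and brute-force BFS oracles
(`bfs_oracle`) used throughout the test suite.

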