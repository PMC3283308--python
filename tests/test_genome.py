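"""Genome representation, text format, reductions and totalization."""

import pytest

from dedouble.errors import MissingKeyError, NotDedoubledError, ParseError
from dedouble.genome import (
    BAR,
    PLAIN,
    TELOMERE,
    Adjacency,
    Marker,
    adjacencies,
    canonical_form,
    classify,
    expand_ancestor,
    genome_from_adjacencies,
    genomes_equivalent,
    is_dedoubled,
    parse_genome,
    reduce_dedoubled,
    swap_copy_labels,
    totalize,
    write_genome,
)
from dedouble.simulate import (
    bfs_oracle,
    random_ancestor,
    random_bd_evolution,
)
from dedouble.dcj import dcj_distance


class TestParsing:
    def test_linear_chromosome(self):
        g = parse_genome("L 1 2 2' 1'")
        assert len(g.chromosomes) == 1 and not g.chromosomes[0].circular
        assert g.chromosomes[0].markers == (
            Marker(1), Marker(2), Marker(2, BAR), Marker(1, BAR))

    def test_circular_chromosome(self):
        g = parse_genome("C 1 2 1' 2'")
        assert g.chromosomes[0].circular

    def test_comments_blank_lines_and_signs(self):
        g = parse_genome("# header\nL -1 2  # trailing\n\nC -3' 3\n")
        assert len(g.chromosomes) == 2
        assert g.chromosomes[0].markers[0].sign == -1

    @pytest.mark.parametrize("bad", [
        "L 1 1 1",          # three occurrences
        "L 1 1",            # two plain copies
        "L 1' 2 1'",        # two bar copies
        "L 0",              # family must be positive
        "X 1 2",            # bad shape letter
        "L",                # empty chromosome
        "",                 # no chromosomes
        "L 1a",             # bad token
    ])
    def test_parse_errors(self, bad):
        with pytest.raises(ParseError):
            parse_genome(bad)

    def test_copy_labels_canonicalized_to_first_occurrence(self):
        g = parse_genome("L 1' 2 1")
        assert g.chromosomes[0].markers[0].copy == PLAIN
        assert g.chromosomes[0].markers[2].copy == BAR

    def test_roundtrip_on_seeded_random_genomes(self):
        for seed in range(200):
            anc = random_ancestor(1 + seed % 7, chromosomes=1 + seed % 2,
                                  circular_fraction=0.3, seed=seed)
            rec = random_bd_evolution(anc, seed % 5, "dcj", seed=seed)
            g = rec.derived
            assert genomes_equivalent(parse_genome(write_genome(g)), g)


class TestAdjacencies:
    def test_linear_counts_and_telomeres(self):
        g = parse_genome("L 1 2")
        assert adjacencies(g) == {
            Adjacency(TELOMERE, Marker(1)),
            Adjacency(Marker(1), Marker(2)),
            Adjacency(Marker(2), TELOMERE),
        }

    def test_circular_counts(self):
        g = parse_genome("C 1 2 1' 2'")
        assert len(adjacencies(g)) == 4

    def test_equivalent_writings_are_one_adjacency(self):
        assert Adjacency(Marker(1), Marker(2)) == \
            Adjacency(-Marker(2), -Marker(1))

    def test_dedoubled_adjacency_present(self):
        g = parse_genome("L 1 2 2' 1'")
        assert Adjacency(Marker(2), Marker(2, BAR)) in adjacencies(g)
        assert len(adjacencies(g)) == 5

    def test_reading_direction_invariance(self):
        g = parse_genome("L 1 -2 3'  # canonicalized to plain\nC 4 -5")
        flipped = parse_genome("L -3' 2 -1\nC 5 -4")
        assert adjacencies(g) == adjacencies(flipped)

    def test_rebuild_inverts_adjacency_extraction(self):
        for seed in range(30):
            anc = random_ancestor(2 + seed % 6, chromosomes=1 + seed % 3,
                                  circular_fraction=0.4, seed=seed)
            rec = random_bd_evolution(anc, seed % 4, "dcj", seed=seed + 1)
            g = rec.derived
            assert genomes_equivalent(genome_from_adjacencies(adjacencies(g)), g)


class TestClassification:
    @pytest.mark.parametrize("text,kind,dedoubled", [
        ("L 1 1' 2 2'", "totally_duplicated", True),
        ("L 1 -1' 2 2'", "totally_duplicated", False),   # inverted form (x -x')
        ("L 1 2 2' 1'", "totally_duplicated", False),    # couple 1 not adjacent
        ("L 1 2 3", "non_duplicated", True),
        ("L 1 1' 2", "duplicated", True),
        ("L -2' -2", "totally_duplicated", True),        # (-x' -x) == (x x')
        ("C 1 1'", "totally_duplicated", True),          # sorted via the wrap
    ])
    def test_kinds_and_dedoubled_flag(self, text, kind, dedoubled):
        assert classify(parse_genome(text)) == (kind, dedoubled)


class TestReduction:
    def test_collapses_sorted_couples(self):
        assert genomes_equivalent(
            reduce_dedoubled(parse_genome("L 1 1' 2 2'")), parse_genome("L 1 2"))

    def test_negative_pair_reduces_to_negative_marker(self):
        g = reduce_dedoubled(parse_genome("L 3 -2 -2' 4"))
        assert g.chromosomes[0].markers[1] == Marker(2, PLAIN, -1)

    def test_not_dedoubled_raises(self):
        with pytest.raises(NotDedoubledError):
            reduce_dedoubled(parse_genome("L 1 -1'"))

    def test_circular_pair_across_the_wrap(self):
        g = reduce_dedoubled(parse_genome("C 1' 2 2' 1"))
        assert genomes_equivalent(g, parse_genome("C 1 2"))


class TestTotalization:
    def test_run_replaced_by_sorted_couple(self):
        g = parse_genome("L 1 1' 5 6 7 2 2'")
        total, runmap = totalize(g)
        assert genomes_equivalent(total, parse_genome("L 1 1' 5 5' 2 2'"))
        assert runmap == {5: (Marker(5), Marker(6), Marker(7))}

    def test_fully_non_duplicated_single_run(self):
        total, runmap = totalize(parse_genome("L 1 2 3"))
        assert genomes_equivalent(total, parse_genome("L 1 1'"))
        assert set(runmap) == {1}

    def test_negative_run_head_gives_negative_pair(self):
        total, _ = totalize(parse_genome("L 1 1' -4 -5 2 2'"))
        ms = total.chromosomes[0].markers
        assert ms[2] == Marker(4, PLAIN, -1) and ms[3] == Marker(4, BAR, -1)
        assert is_dedoubled(total)

    def test_already_total_is_identity(self):
        g = parse_genome("L 1 2 2' 1'")
        total, runmap = totalize(g)
        assert total == g and runmap == {}

    def test_expand_inverts_totalize_after_reduction(self):
        # identity on non-duplicated genomes: totalize introduces
        # couples, reduction collapses them, expansion restores the runs
        for text in ["L 1 2 3", "L 3 -4 5\nC 6 7", "L -2 1\nL 5"]:
            g = parse_genome(text)
            total, runmap = totalize(g)
            assert is_dedoubled(total)
            back = expand_ancestor(reduce_dedoubled(total), runmap)
            assert genomes_equivalent(back, g)

    def test_expand_flipped_key_splices_reversed_run(self):
        runmap = {5: (Marker(5), Marker(6), Marker(7))}
        g = expand_ancestor(parse_genome("L 2 -5"), runmap)
        assert g.chromosomes[0].markers == (
            Marker(2), Marker(7, sign=-1), Marker(6, sign=-1), Marker(5, sign=-1))

    def test_expand_missing_key_raises(self):
        with pytest.raises(MissingKeyError):
            expand_ancestor(parse_genome("L 1 2"), {9: (Marker(9),)})

    def test_totalize_preserves_dedoubling_distance(self):
        """Totalization contract: the distance to the nearest dedoubled
        genome is unchanged, and equals the closed formula on the
        totalized genome (tiny instances, brute-force reference)."""
        cases = [
            "L 1 3 2 2' 1'", "L 1 2 1' 3", "L 1 -1' 3 2 2'",
            "L 1 5 6 2 2' 1'", "L 3 1 2 1' 2'", "L 1 2 2' 1' 3",
            "C 1 3 2 2' 1'", "L 1 2\nL 3 1' 2'",
        ]
        for text in cases:
            g = parse_genome(text)
            total, _ = totalize(g)
            d_g = bfs_oracle(g, "dcj", limit=4)
            d_t = bfs_oracle(total, "dcj", limit=4)
            assert d_g == d_t == dcj_distance(total).distance, text


class TestCanonicalizationProperties:
    """Hypothesis-generated genomes: serialization and adjacency
    canonicalization are involutive and symmetry-respecting."""

    from hypothesis import given, settings, strategies as st

    @st.composite
    def genomes(draw, st=st):
        n = draw(st.integers(min_value=1, max_value=5))
        markers = []
        for f in range(1, n + 1):
            copies = draw(st.integers(min_value=1, max_value=2))
            for c in range(copies):
                markers.append(Marker(f, c, draw(st.sampled_from((1, -1)))))
        order = draw(st.permutations(markers))
        n_chrom = draw(st.integers(min_value=1, max_value=min(2, len(order))))
        cut = len(order) // 2 if n_chrom == 2 else len(order)
        chroms = []
        for part in ([order[:cut], order[cut:]] if n_chrom == 2 else [order]):
            if not part:
                continue
            from dedouble.genome import Chromosome
            chroms.append(Chromosome(tuple(part),
                                     circular=draw(st.booleans())))
        from dedouble.genome import Genome
        return Genome(tuple(chroms))

    @given(genomes())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_write_parse_roundtrip(self, g):
        assert genomes_equivalent(parse_genome(write_genome(g)), g)

    @given(genomes())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_reflection_leaves_adjacency_set_unchanged(self, g):
        from dedouble.genome import Genome
        flipped = Genome(tuple(c.reversed() for c in g.chromosomes))
        assert adjacencies(flipped) == adjacencies(g)


class TestCopySwapInvariance:
    def test_distance_invariant_under_label_swap(self):
        for seed in range(20):
            anc = random_ancestor(4, seed=seed)
            rec = random_bd_evolution(anc, 3, "dcj", seed=seed + 50)
            g, _ = totalize(rec.derived)
            fams = sorted(g.duplicated_families())
            swapped = swap_copy_labels(g, fams[: 1 + seed % len(fams)])
            assert dcj_distance(g).distance == dcj_distance(swapped).distance
            assert canonical_form(g) == canonical_form(swapped)
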