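"""Overlap graph, sorting reversals, reversal distances and scenarios."""

import random

import pytest

from dedouble.dcj import dcj_distance, dcj_distance_linear
from dedouble.errors import UnorientedGenomeError, UnorientedVertex
from dedouble.genome import (
    genomes_equivalent,
    is_dedoubled,
    parse_genome,
    totalize,
)
from dedouble.rearrange import apply_scenario, reverse_segment
from dedouble.reversal import (
    apply_rho,
    build_overlap_graph,
    is_oriented,
    local_complement,
    orientation_status,
    reversal_distance,
    reversal_sort,
    to_dot,
    transform_reversal,
    vertex_score,
)
from dedouble.simulate import bfs_oracle, random_ancestor, random_bd_evolution


def overlap_graphs_equal(a, b):
    if a.edges != b.edges:
        return False
    return all(
        (a.vertices[f].oriented, a.vertices[f].sorted) ==
        (b.vertices[f].oriented, b.vertices[f].sorted)
        for f in a.vertices)


def oriented_linear_instance(seed, n_max=6, k_max=5):
    rng = random.Random(seed)
    anc = random_ancestor(2 + seed % (n_max - 1), seed=seed)
    rec = random_bd_evolution(anc, 1 + rng.randrange(k_max), "reversal",
                              seed=seed + 1, oriented_only=True)
    g, _ = totalize(rec.derived)
    return g


class TestOverlapGraph:
    def test_published_genome_has_four_oriented_components(self, fixtures):
        og = build_overlap_graph(fixtures["published26"])
        comps = og.components()
        assert len(comps) == 4
        assert sorted(map(sorted, comps)) == [
            [1, 2], [3, 4, 5, 6, 9, 10], [7, 8], [11, 12, 13]]
        status, offending = orientation_status(og)
        assert status == "oriented" and not offending
        for comp in comps:
            assert any(og.vertices[f].oriented for f in comp)

    def test_disjoint_intervals_no_edge(self):
        og = build_overlap_graph(parse_genome("L 1 -1' 2 2'"))
        assert og.vertices[1].interval == (1, 2)
        assert og.vertices[2].interval == (3, 4)
        assert not og.edges
        assert og.vertices[1].oriented and not og.vertices[1].sorted
        assert og.vertices[2].sorted

    def test_properly_crossing_intervals_share_an_edge(self):
        og = build_overlap_graph(parse_genome("L 1 -2 -1' -2'"))
        assert og.edges == {frozenset({1, 2})}
        assert og.vertices[1].oriented and not og.vertices[2].oriented

    def test_containment_is_not_overlap(self):
        # couple 2 nested inside couple 1: no edge
        og = build_overlap_graph(parse_genome("L 1 2 -2' -1'"))
        assert frozenset({1, 2}) not in og.edges

    def test_orientation_statuses(self):
        assert orientation_status(build_overlap_graph(
            parse_genome("L 1 2 1' 2'")))[0] == "unoriented"
        # dedoubled: vacuously oriented (all vertices sorted)
        assert orientation_status(build_overlap_graph(
            parse_genome("L 1 1' 2 2'")))[0] == "oriented"


class TestSortingReversals:
    def test_rho_and_rho_bar_produce_sorted_forms(self):
        g = parse_genome("L 1 -1' 2 2'")
        assert genomes_equivalent(apply_rho(g, 1, "rho"),
                                  parse_genome("L 1 1' 2 2'"))
        assert genomes_equivalent(apply_rho(g, 1, "rho_bar"),
                                  parse_genome("L -1 -1' 2 2'"))

    def test_unoriented_vertex_rejected(self):
        g = parse_genome("L 1 2 1' 2'")
        with pytest.raises(UnorientedVertex):
            apply_rho(g, 1)
        with pytest.raises(UnorientedVertex):
            vertex_score(parse_genome("L 1 1' 2 2'"), 1)  # sorted vertex

    def test_scores_on_worked_examples(self):
        assert vertex_score(parse_genome("L 1 -1' 2 2'"), 1) == 0
        assert vertex_score(parse_genome("L 1 -2 -1' -2'"), 1) == 1

    def test_score_identical_for_both_variants(self):
        checked = 0
        for seed in range(80):
            g = oriented_linear_instance(seed)
            og = build_overlap_graph(g)
            for f, v in og.vertices.items():
                if not v.oriented or v.sorted:
                    continue
                after_rho = build_overlap_graph(apply_rho(g, f, "rho"))
                after_bar = build_overlap_graph(apply_rho(g, f, "rho_bar"))
                count = lambda og_: sum(1 for u in og_.vertices.values()
                                        if u.oriented and not u.sorted)
                assert count(after_rho) == count(after_bar), (seed, f)
                checked += 1
        assert checked >= 100

    def test_local_complementation_matches_rebuild(self):
        """Graph-transform route (complement N[v], flip orientations)
        equals rebuilding the overlap graph from the reversed genome."""
        checked = 0
        for seed in range(100):
            g = oriented_linear_instance(seed)
            og = build_overlap_graph(g)
            for f, v in sorted(og.vertices.items()):
                if not v.oriented or v.sorted:
                    continue
                for variant in ("rho", "rho_bar"):
                    lc = local_complement(og, f, variant)
                    rb = build_overlap_graph(apply_rho(g, f, variant))
                    assert overlap_graphs_equal(lc, rb), (seed, f, variant)
                    checked += 1
        assert checked >= 300

    def test_interval_transform_matches_rebuild_for_any_reversal(self):
        rng = random.Random(0)
        for seed in range(40):
            g = oriented_linear_instance(seed)
            L = len(g.chromosomes[0].markers)
            s = rng.randrange(1, L + 1)
            e = rng.randrange(s, L + 1)
            og = build_overlap_graph(g)
            assert overlap_graphs_equal(
                transform_reversal(og, s, e),
                build_overlap_graph(reverse_segment(g, 0, s, e)))


class TestDistance:
    @pytest.mark.parametrize("text,d", [
        ("L 1 -1' 2 2'", 1),
        ("L 1 -2 -1' -2'", 2),
        ("L 1 1' 2 2'", 0),
    ])
    def test_worked_values(self, text, d):
        assert reversal_distance(parse_genome(text)).distance == d

    def test_unoriented_genome_rejected(self):
        with pytest.raises(UnorientedGenomeError):
            reversal_distance(parse_genome("L 1 2 1' 2'"))

    def test_equals_linear_dcj_distance_when_oriented(self):
        for seed in range(30):
            g = oriented_linear_instance(seed)
            assert reversal_distance(g).distance == dcj_distance_linear(g).distance
            assert dcj_distance(g).distance <= reversal_distance(g).distance

    def test_matches_bfs_oracle_on_small_instances(self):
        for seed in range(12):
            anc = random_ancestor(2, seed=seed)
            rec = random_bd_evolution(anc, 2, "reversal", seed=seed + 3,
                                      oriented_only=True)
            g, _ = totalize(rec.derived)
            assert reversal_distance(g).distance == bfs_oracle(g, "reversal")


class TestSort:
    def test_dedoubled_input_gives_empty_scenario(self):
        sc, end, rep = reversal_sort(parse_genome("L 1 1' 2 2'"))
        assert len(sc) == 0 and rep.distance == 0

    def test_two_reversal_worked_scenario(self):
        g = parse_genome("L 1 -2 -1' -2'")
        sc, end, rep = reversal_sort(g)
        assert len(sc) == 2
        assert is_dedoubled(end) and end.unichromosomal_linear
        assert genomes_equivalent(apply_scenario(g, sc), end)

    def test_scenarios_meet_formula_and_stay_oriented(self):
        """Length n - C + 2m; every intermediate is a single linear
        chromosome and remains oriented (merging reversals never strand
        an unoriented component)."""
        for seed in range(40):
            g = oriented_linear_instance(seed)
            sc, end, rep = reversal_sort(g)
            assert len(sc) == rep.distance == reversal_distance(g).distance
            assert is_dedoubled(end) and end.unichromosomal_linear
            state = g
            for op in sc:
                state = apply_scenario(state, [op])
                assert state.unichromosomal_linear
                assert is_oriented(state)
            assert genomes_equivalent(state, end)

    def test_each_step_decreases_exact_distance(self):
        for seed in range(20):
            g = oriented_linear_instance(seed)
            sc, _, rep = reversal_sort(g)
            state, d = g, rep.distance
            for op in sc:
                state = apply_scenario(state, [op])
                d -= 1
                assert dcj_distance_linear(state).distance == d

    def test_published_genome_sorts_to_a_dedoubled_chromosome(self, fixtures):
        g = fixtures["published26"]
        sc, end, rep = reversal_sort(g)
        assert len(sc) == rep.distance == reversal_distance(g).distance
        assert is_dedoubled(end) and end.unichromosomal_linear


def test_dot_export_marks_oriented_vertices(fixtures):
    og = build_overlap_graph(fixtures["published26"])
    dot = to_dot(og)
    assert dot.count("fillcolor=gray") == sum(
        1 for v in og.vertices.values() if v.oriented)
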