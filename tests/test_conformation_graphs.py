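import itertools

import numpy as np
import pytest

from tunnelflex.conformation_graphs import (
    amino_collision_cliques,
    build_collision_free_graph,
    build_collision_graph,
    build_temporary_graph,
    local_valid_conformations,
    maximal_cliques,
)
from tunnelflex.geometry import spheres_touch
from tunnelflex.pipeline import enumerate_conformations
from tunnelflex.rotamers import rotamers_collide

A2, A3, A5 = ("A", 2, ""), ("A", 3, ""), ("A", 5, "")


def brute_force_maximal_cliques(vertices, edges):
    """2^n subset enumeration: a maximal clique is a complete subset not
    strictly contained in any other complete subset."""
    vertices = sorted(vertices)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(
            frozenset((a, b)) in edge_set
            for a, b in itertools.combinations(sub, 2)
        )

    cliques = [
        frozenset(sub)
        for k in range(1, len(vertices) + 1)
        for sub in itertools.combinations(vertices, k)
        if is_clique(sub)
    ]
    maximal = [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]
    return sorted(tuple(sorted(c)) for c in maximal)


class TestMaximalCliques:
    def test_triangle(self):
        got = maximal_cliques([1, 2, 3], [(1, 2), (2, 3), (1, 3)])
        assert got == [(1, 2, 3)]

    def test_edgeless_graph_gives_singletons(self):
        assert maximal_cliques([1, 2, 3, 4], []) == [(1,), (2,), (3,), (4,)]

    def test_matches_subset_enumeration_on_random_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 13))
            vertices = list(range(n))
            edges = [
                (i, j)
                for i, j in itertools.combinations(vertices, 2)
                if rng.random() < 0.4
            ]
            assert maximal_cliques(vertices, edges) == (
                brute_force_maximal_cliques(vertices, edges)
            )


class TestResidueGraphs:
    def test_tg_edges_equal_all_pairs_bsv_scan(self, toy_cache):
        _, molecule, tunnel = toy_cache(n_residues=5, packing=0.8, seed=2)
        res = enumerate_conformations(molecule, tunnel)
        adj = res.adjacent
        tg = build_temporary_graph(adj)
        for a, b in itertools.combinations(adj.residues, 2):
            expect = spheres_touch(
                adj.rotamer_sets[a].bsv, adj.rotamer_sets[b].bsv
            )
            assert tg.has_edge(a, b) == expect

    def test_cg_subset_of_tg_and_equals_unfiltered_scan(self, toy_cache):
        """CG edges from the BSV-filtered build equal an all-pairs rotamer
        scan with no TG pre-filter — the broad phase loses nothing."""
        for seed, packing in [(1, 0.9), (2, 1.0), (5, 0.85)]:
            _, molecule, tunnel = toy_cache(
                n_residues=4, packing=packing, seed=seed
            )
            res = enumerate_conformations(molecule, tunnel)
            adj = res.adjacent
            tg = build_temporary_graph(adj)
            cg = build_collision_graph(adj, tg)
            assert cg.edges <= tg.edges
            for a, b in itertools.combinations(adj.residues, 2):
                expect = any(
                    rotamers_collide(x, y)
                    for x in adj.rotamer_sets[a].rotamers
                    for y in adj.rotamer_sets[b].rotamers
                )
                assert cg.has_edge(a, b) == expect

    def test_tg_without_edges_gives_cg_without_edges(self, toy_cache):
        _, molecule, tunnel = toy_cache(n_residues=4, packing=0.0, seed=0)
        res = enumerate_conformations(molecule, tunnel)
        tg = build_temporary_graph(res.adjacent)
        cg = build_collision_graph(res.adjacent, tg)
        assert tg.edges == frozenset() and cg.edges == frozenset()

    def test_cross_clique_pairs_never_collide(self, toy_cache):
        """Residues in different amino-collision cliques (outside any shared
        membership) have no colliding rotamer pair at all."""
        for seed in (0, 1, 3, 4):
            _, molecule, tunnel = toy_cache(n_residues=5, packing=1.0, seed=seed)
            res = enumerate_conformations(molecule, tunnel)
            adj = res.adjacent
            membership = {k: set() for k in adj.residues}
            for c in res.cliques:
                for k in c.members:
                    membership[k].add(c.index)
            for a, b in itertools.combinations(adj.residues, 2):
                if membership[a] & membership[b]:
                    continue  # share a clique: collisions allowed
                for x in adj.rotamer_sets[a].rotamers:
                    for y in adj.rotamer_sets[b].rotamers:
                        assert not rotamers_collide(x, y)


class TestWorkedExample:
    def test_single_amino_collision_clique(self, worked_pipeline):
        assert [sorted(c.members) for c in worked_pipeline.cliques] == [
            [A2, A3, A5]
        ]

    def test_fg_edges_are_all_pairs_minus_three(self, worked_graph):
        fg = worked_graph.fg
        assert len(fg.vertices) == 7  # survivors: 2 + 2 + 3
        assert len(fg.edges) == 16 - 3
        for bad in worked_graph.colliding_pairs:
            assert bad not in fg.edges

    def test_geometric_fg_matches_abstract_fg(self, worked_graph, worked_pipeline):
        clique = worked_pipeline.cliques[0]
        fg = build_collision_free_graph(clique, worked_pipeline.adjacent)
        assert fg.vertices == worked_graph.fg.vertices
        assert fg.edges == worked_graph.fg.edges

    def test_six_local_conformations(self, worked_graph):
        ls = local_valid_conformations(
            worked_graph.fg, worked_graph.clique, worked_graph.adjacent
        )
        assert ls.count == 6

    def test_size_two_clique_rejected(self, worked_graph):
        """(A2.R2, A5.R0) is a maximal clique of size 2: every A3 rotamer
        collides with one of them, so it yields no valid conformation."""
        cliques = maximal_cliques(worked_graph.fg.vertices, worked_graph.fg.edges)
        size2 = [c for c in cliques if len(c) == 2]
        assert size2 == [(((A2), 2), ((A5), 0))]
        ls = local_valid_conformations(
            worked_graph.fg, worked_graph.clique, worked_graph.adjacent
        )
        pos = {k: worked_graph.adjacent.position(k) for k in (A2, A5)}
        for conf in ls.conformations:
            assert not (conf[pos[A2]] == 2 and conf[pos[A5]] == 0)

    def test_local_conformations_equal_product_space_oracle(self, worked_graph):
        """Independent oracle: filter the full rotamer product of the clique
        members by the planted pairwise collision relations."""
        surv = worked_graph.surviving
        keys = sorted(surv)
        valid = []
        for combo in itertools.product(*(surv[k] for k in keys)):
            assignment = dict(zip(keys, combo))
            ok = all(
                frozenset(((a, assignment[a]), (b, assignment[b])))
                not in worked_graph.colliding_pairs
                for a, b in itertools.combinations(keys, 2)
            )
            if ok:
                valid.append(
                    tuple(assignment[k] for k in worked_graph.adjacent.residues)
                )
        ls = local_valid_conformations(
            worked_graph.fg, worked_graph.clique, worked_graph.adjacent
        )
        assert sorted(valid) == sorted(ls.conformations)


class TestSingletonClique:
    def test_isolated_residue_yields_one_conformation_per_rotamer(self, toy_cache):
        _, molecule, tunnel = toy_cache(n_residues=3, packing=0.0, seed=1)
        res = enumerate_conformations(molecule, tunnel)
        for clique, ls in zip(res.cliques, res.local_sets):
            if len(clique.members) == 1:
                (key,) = clique.members
                fg = build_collision_free_graph(clique, res.adjacent)
                assert fg.edges == frozenset()  # no inter-residue pairs
                assert ls.count == len(res.adjacent.rotamer_sets[key].rotamers)


class TestLocalSoundness:
    def test_local_conformations_are_collision_free_as_atoms(self, toy_cache):
        _, molecule, tunnel = toy_cache(n_residues=5, packing=1.0, seed=2)
        res = enumerate_conformations(molecule, tunnel)
        for ls in res.local_sets:
            members = sorted(ls.members)
            for conf in ls.conformations:
                chosen = {
                    k: res.adjacent.rotamer_sets[k].by_index(
                        conf[res.adjacent.position(k)]
                    )
                    for k in members
                }
                for a, b in itertools.combinations(members, 2):
                    assert not rotamers_collide(chosen[a], chosen[b])
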