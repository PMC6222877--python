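"""Collision graphs, maximal cliques, and local valid conformations.

The pipeline localizes collision handling in three graph stages:

1. a *temporary graph* TG over the tunnel-adjacent residues, with an edge
   wherever two BSVs overlap (cheap broad phase);
2. the *collision graph* CG, keeping only TG edges where at least one
   rotamer pair actually collides (exact narrow phase — pairs outside TG
   need no scan, because disjoint BSVs certify collision-freeness);
3. per maximal clique of CG (an *amino-collision clique*), a rotamer-level
   *collision-free graph* FG_k whose edges are the non-colliding
   inter-residue rotamer pairs.

A maximal clique of FG_k that covers every residue of the amino-collision
clique assigns exactly one rotamer per residue with no pairwise collision:
a *local valid conformation*.  Residues in different cliques (outside any
shared membership) can never collide, which is what lets local solutions be
combined independently later.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import networkx as nx

from .geometry import DEFAULT_TOL, spheres_touch
from .model_io import ResidueKey
from .rotamers import AdjacentSet, rotamers_collide

#: (residue key, rotamer index) — a vertex of a collision-free graph.
RotamerVertex = tuple[ResidueKey, int]


@dataclass(frozen=True)
class ResidueGraph:
    """Undirected residue-level graph (the BSV-overlap TG or the CG)."""

    vertices: frozenset
    edges: frozenset
    kind: Literal["temporary", "collision"]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("edges must be 2-element frozensets")

    def has_edge(self, a: ResidueKey, b: ResidueKey) -> bool:
        return frozenset((a, b)) in self.edges


@dataclass(frozen=True)
class AminoCollisionClique:
    """A maximal clique of the collision graph."""

    index: int
    members: frozenset


@dataclass(frozen=True)
class CollisionFreeGraph:
    """Rotamer-level graph FG_k for one amino-collision clique."""

    clique_index: int
    vertices: frozenset
    edges: frozenset


@dataclass(frozen=True)
class LocalConformationSet:
    """All local valid conformations of one amino-collision clique, as
    full-length conformation vectors with -1 outside the clique."""

    clique_index: int
    conformations: tuple
    members: frozenset

    @property
    def count(self) -> int:
        return len(self.conformations)


def build_temporary_graph(adjacent: AdjacentSet, tol: float = DEFAULT_TOL) -> ResidueGraph:
    """Edge iff the two residues' BSVs overlap."""
    keys = adjacent.residues
    edges = set()
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            bi = adjacent.rotamer_sets[keys[i]].bsv
            bj = adjacent.rotamer_sets[keys[j]].bsv
            # inclusive of tangency: a touching BSV pair must still fall
            # through to the exact rotamer scan (broad phase is conservative)
            if spheres_touch(bi, bj, tol):
                edges.add(frozenset((keys[i], keys[j])))
    return ResidueGraph(
        vertices=frozenset(keys), edges=frozenset(edges), kind="temporary"
    )


def build_collision_graph(
    adjacent: AdjacentSet, tg: ResidueGraph, tol: float = DEFAULT_TOL
) -> ResidueGraph:
    """Keep a TG edge iff at least one rotamer pair across it collides."""
    edges = set()
    for e in tg.edges:
        a, b = sorted(e)
        ra = adjacent.rotamer_sets[a].rotamers
        rb = adjacent.rotamer_sets[b].rotamers
        if any(
            rotamers_collide(x, y, tol) for x in ra for y in rb
        ):
            edges.add(frozenset((a, b)))
    return ResidueGraph(
        vertices=tg.vertices, edges=frozenset(edges), kind="collision"
    )


def maximal_cliques(vertices: Iterable, edges: Iterable) -> list[tuple]:
    """All maximal cliques of a simple undirected graph, sorted.

    Bron–Kerbosch with pivoting (networkx ``find_cliques``); isolated
    vertices come out as singleton cliques.  Output is a sorted list of
    sorted vertex tuples, so results are deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(vertices)
    g.add_edges_from(tuple(e) for e in edges)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    return sorted(cliques)


def amino_collision_cliques(cg: ResidueGraph) -> list[AminoCollisionClique]:
    """Maximal cliques of the collision graph, indexed in sorted order."""
    cliques = maximal_cliques(cg.vertices, cg.edges)
    return [
        AminoCollisionClique(index=k, members=frozenset(c))
        for k, c in enumerate(cliques)
    ]


def build_collision_free_graph(
    clique: AminoCollisionClique,
    adjacent: AdjacentSet,
    tol: float = DEFAULT_TOL,
) -> CollisionFreeGraph:
    """FG_k: all surviving rotamers of the clique's residues as vertices,
    an edge for every collision-free inter-residue rotamer pair."""
    members = sorted(clique.members)
    vertices: set[RotamerVertex] = set()
    for key in members:
        for rot in adjacent.rotamer_sets[key].rotamers:
            vertices.add((key, rot.index))
    edges: set[frozenset] = set()
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            for x in adjacent.rotamer_sets[members[i]].rotamers:
                for y in adjacent.rotamer_sets[members[j]].rotamers:
                    if not rotamers_collide(x, y, tol):
                        edges.add(
                            frozenset(
                                ((members[i], x.index), (members[j], y.index))
                            )
                        )
    return CollisionFreeGraph(
        clique_index=clique.index,
        vertices=frozenset(vertices),
        edges=frozenset(edges),
    )


def local_valid_conformations(
    fg: CollisionFreeGraph,
    clique: AminoCollisionClique,
    adjacent: AdjacentSet,
) -> LocalConformationSet:
    """Local valid conformations of one clique.

    A maximal clique of FG_k with as many vertices as the amino-collision
    clique has residues necessarily picks one rotamer per residue, all
    pairwise collision-free; smaller maximal cliques leave some residue
    without a compatible rotamer and are rejected.  Each kept clique is
    encoded as a full-length conformation vector with -1 outside the
    residue clique.
    """
    want = len(clique.members)
    confs = []
    for fg_clique in maximal_cliques(fg.vertices, fg.edges):
        if len(fg_clique) != want:
            continue
        vec = [-1] * adjacent.n
        for key, rot_index in fg_clique:
            vec[adjacent.position(key)] = rot_index
        confs.append(tuple(vec))
    return LocalConformationSet(
        clique_index=clique.index,
        conformations=tuple(sorted(confs)),
        members=clique.members,
    )
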