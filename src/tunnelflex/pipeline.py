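"""End-to-end pipeline: structure + tunnel → all valid conformations →
maximum bottleneck.

This is the glue the CLI and the examples use; each stage remains
individually importable for finer control.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bottleneck_analysis import BottleneckReport, analyze
from .conformation_graphs import (
    AminoCollisionClique,
    LocalConformationSet,
    amino_collision_cliques,
    build_collision_free_graph,
    build_collision_graph,
    build_temporary_graph,
    local_valid_conformations,
)
from .enumeration import GlobalConformationSet, combine_all
from .geometry import DEFAULT_TOL
from .model_io import Molecule
from .rotamers import AdjacentSet, generate_rotamers, remove_invalid_rotamers
from .tunnel import TunnelProfile, tunnel_adjacent_residues


@dataclass(frozen=True)
class EnumerationResult:
    """Everything the enumeration stage produced, for inspection."""

    adjacent: AdjacentSet
    cliques: tuple
    local_sets: tuple
    global_conformations: GlobalConformationSet


def enumerate_conformations(
    molecule: Molecule,
    tunnel: TunnelProfile,
    step: float = 30.0,
    tol: float = DEFAULT_TOL,
    self_main_chain: bool = True,
    max_conformations: int | None = None,
) -> EnumerationResult:
    """Run the full enumeration: adjacency, pruning, graphs, combination."""
    rotamer_sets = {
        res.key: generate_rotamers(res, step=step) for res in molecule.residues
    }
    adjacent = tunnel_adjacent_residues(molecule, rotamer_sets, tunnel, tol=tol)
    adjacent = remove_invalid_rotamers(
        adjacent, molecule, tol=tol, self_main_chain=self_main_chain
    )
    tg = build_temporary_graph(adjacent, tol=tol)
    cg = build_collision_graph(adjacent, tg, tol=tol)
    cliques = amino_collision_cliques(cg)
    local_sets: list[LocalConformationSet] = []
    for clique in cliques:
        fg = build_collision_free_graph(clique, adjacent, tol=tol)
        local_sets.append(local_valid_conformations(fg, clique, adjacent))
    globals_ = combine_all(
        local_sets, adjacent, max_conformations=max_conformations
    )
    return EnumerationResult(
        adjacent=adjacent,
        cliques=tuple(cliques),
        local_sets=tuple(local_sets),
        global_conformations=globals_,
    )


def max_bottleneck_analysis(
    molecule: Molecule,
    tunnel: TunnelProfile,
    step: float = 30.0,
    tol: float = DEFAULT_TOL,
    self_main_chain: bool = True,
    max_conformations: int | None = None,
    r_cap: float | None = None,
) -> tuple[EnumerationResult, BottleneckReport]:
    """Enumerate all valid conformations, then find the maximum bottleneck."""
    result = enumerate_conformations(
        molecule,
        tunnel,
        step=step,
        tol=tol,
        self_main_chain=self_main_chain,
        max_conformations=max_conformations,
    )
    report = analyze(
        tunnel,
        result.global_conformations,
        result.adjacent,
        molecule,
        r_cap=r_cap,
    )
    return result, report
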