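"""Combining local valid conformations into all global valid conformations.

Local solutions (one per amino-collision clique) are merged by a depth-first
recursion over the cliques: at each level, the partial assignment built so
far is checked for *compatibility* with the candidate local conformation —
no position may carry two different rotamer indices — and incompatible
branches are pruned immediately.  Because residues in different cliques
(outside shared members) provably cannot collide, every surviving full
assignment is globally collision-free.  Memory grows with the number of
local conformations, not with their product.

A product-space brute-force enumerator over all rotamer tuples is provided
as an independent verification oracle for small inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from .conformation_graphs import LocalConformationSet
from .geometry import DEFAULT_TOL
from .rotamers import AdjacentSet, rotamers_collide

#: A conformation vector: entry i is a rotamer index for residue i of the
#: adjacent set, or -1 when the (partial) conformation leaves it free.
ConformationVector = tuple[int, ...]


@dataclass(frozen=True)
class GlobalConformationSet:
    """All distinct, fully-assigned, collision-free conformation vectors."""

    conformations: tuple
    n_residues: int

    def __post_init__(self) -> None:
        for c in self.conformations:
            if len(c) != self.n_residues or any(x < 0 for x in c):
                raise ValueError(f"not a fully assigned conformation: {c}")

    @property
    def count(self) -> int:
        return len(self.conformations)


def compatible(a: Sequence[int], b: Sequence[int]) -> bool:
    """True iff no position carries two different non-sentinel indices.

    Rotamer index 0 (the input pose) is a perfectly valid assignment, so
    the test is on ``>= 0``, with -1 as the only neutral value.
    """
    if len(a) != len(b):
        raise ValueError("conformation vectors differ in length")
    return all(not (x >= 0 and y >= 0 and x != y) for x, y in zip(a, b))


def merge(a: Sequence[int], b: Sequence[int]) -> ConformationVector:
    """Positionwise union of two compatible partial conformations."""
    if not compatible(a, b):
        raise ValueError("cannot merge incompatible conformation vectors")
    return tuple(x if x >= 0 else y for x, y in zip(a, b))


def combine_all(
    local_sets: Sequence[LocalConformationSet],
    adjacent: AdjacentSet,
    max_conformations: int | None = None,
) -> GlobalConformationSet:
    """Depth-first combination of local conformations into global ones.

    Cliques are processed largest-first (more constraints earlier means
    earlier pruning; the output is invariant to the order).  Overlapping
    cliques can reach the same full assignment along different branches, so
    the final set is deduplicated and sorted.
    """
    covered: set = set()
    for ls in local_sets:
        covered |= ls.members
    missing = set(adjacent.residues) - covered
    if missing:
        raise ValueError(
            f"local conformation sets cover no clique for residues {sorted(missing)}"
        )

    ordered = sorted(
        local_sets, key=lambda ls: (-len(ls.members), ls.clique_index)
    )
    results: set[ConformationVector] = set()
    empty = tuple([-1] * adjacent.n)

    def recurse(level: int, pre: ConformationVector) -> None:
        if level == len(ordered):
            results.add(pre)
            if max_conformations is not None and len(results) > max_conformations:
                raise RuntimeError(
                    f"enumeration aborted: more than {max_conformations} "
                    "global conformations (raise --max-conformations to "
                    "continue)"
                )
            return
        for current in ordered[level].conformations:
            if compatible(pre, current):
                recurse(level + 1, merge(pre, current))

    if ordered and all(ls.count > 0 for ls in ordered):
        recurse(0, empty)
    # an empty local set for any clique means no global conformation exists
    results = {c for c in results if all(x >= 0 for x in c)}
    return GlobalConformationSet(
        conformations=tuple(sorted(results)), n_residues=adjacent.n
    )


def brute_force_enumerate(
    adjacent: AdjacentSet,
    tol: float = DEFAULT_TOL,
    max_candidates: int = 10**6,
) -> GlobalConformationSet:
    """Direct filtering of the full rotamer product space.

    Iterates every tuple of surviving rotamer indices and keeps exactly
    those with zero inter-residue atom collisions.  Exponential — guarded
    by ``max_candidates`` — and used as the verification oracle for
    :func:`combine_all`.
    """
    keys = adjacent.residues
    per_res = [adjacent.rotamer_sets[k].rotamers for k in keys]
    total = 1
    for rots in per_res:
        total *= len(rots)
    if total > max_candidates:
        raise ValueError(
            f"candidate space {total} exceeds the brute-force bound "
            f"{max_candidates}"
        )

    # Precompute the pairwise collision table once; the tuple loop then only
    # does lookups.
    n = len(keys)
    collides: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            bad = {
                (x.index, y.index)
                for x in per_res[i]
                for y in per_res[j]
                if rotamers_collide(x, y, tol)
            }
            if bad:
                collides[(i, j)] = bad

    valid = []
    pair_items = list(collides.items())
    for combo in itertools.product(*per_res):
        ok = True
        for (i, j), bad in pair_items:
            if (combo[i].index, combo[j].index) in bad:
                ok = False
                break
        if ok:
            valid.append(tuple(r.index for r in combo))
    return GlobalConformationSet(
        conformations=tuple(sorted(valid)), n_residues=adjacent.n
    )
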