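"""Rotamer discretization, bounding-sphere volumes, and invalid-rotamer pruning.

A rotatable side chain is treated as one rigid body spun about the Cα–Cβ
axis in fixed angular steps (default 30°, i.e. 12 rotamers, index 0 being the
pose given in the input structure).  The single-axis model is a deliberate
simplification: the coarse 30° grid stands in for the positions deeper
rotation axes could reach, and it is what makes exhaustive enumeration
tractable (12^n candidates instead of a rotamer tree per residue).

Each residue also carries a Bounding Sphere Volume (BSV): one sphere
containing the residue's main chain and every rotamer.  Disjoint BSVs
certify that no rotamer pair between two residues can ever collide, so all
pairwise machinery downstream only does exact atom scans where BSVs overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import (
    DEFAULT_TOL,
    Sphere,
    enclosing_sphere,
    rotate_points_about_axis,
    swept_bound,
)
from .model_io import AtomSphere, Molecule, Residue, ResidueKey

logger = logging.getLogger(__name__)

#: Atom-name pairs exempt from the rotamer-vs-own-main-chain collision check:
#: Cβ is covalently bonded to Cα (1-2) and sits in forced tetrahedral
#: near-contact with N and C (1-3); these overlaps exist in every pose.
BONDED_EXCLUSIONS = {("CB", "CA"), ("CB", "N"), ("CB", "C")}


@dataclass(frozen=True)
class Rotamer:
    """One rigid rotation of a side chain; index 0 is the input pose."""

    residue_key: ResidueKey
    index: int
    angle: float
    atoms: tuple[AtomSphere, ...]

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.center for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])


@dataclass(frozen=True)
class RotamerSet:
    """All surviving rotamers of one residue plus its BSV."""

    residue_key: ResidueKey
    rotamers: tuple[Rotamer, ...]
    bsv: Sphere

    def __post_init__(self) -> None:
        if not self.rotamers:
            raise ValueError(f"residue {self.residue_key}: empty rotamer set")

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.rotamers]

    def by_index(self, index: int) -> Rotamer:
        for r in self.rotamers:
            if r.index == index:
                return r
        raise KeyError((self.residue_key, index))


@dataclass(frozen=True)
class AdjacentSet:
    """The ordered tunnel-adjacent residues S and their rotamer sets.

    The residue order fixes the conformation-vector position of each
    residue: entry ``i`` of a conformation vector is a rotamer index for
    ``residues[i]`` (or -1 when unconstrained).
    """

    residues: tuple[ResidueKey, ...]
    rotamer_sets: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(sorted(self.residues)))
        missing = [k for k in self.residues if k not in self.rotamer_sets]
        if missing:
            raise ValueError(f"rotamer sets missing for residues {missing}")

    @property
    def n(self) -> int:
        return len(self.residues)

    def position(self, key: ResidueKey) -> int:
        return self.residues.index(key)


class AllRotamersInvalidError(ValueError):
    """Every rotamer of a tunnel-adjacent residue collides with the static
    environment — the input structure already contradicts the sphere model."""


def generate_rotamers(residue: Residue, step: float = 30.0) -> RotamerSet:
    """Discretize a residue's side-chain rotation into 360/step rotamers.

    Rotamer ``j`` is the whole side chain rotated rigidly by ``j * step``
    degrees about the Cα–Cβ axis; non-rotatable residues get the single
    input-pose rotamer.  The BSV merges per-atom swept bounds (rotatable) or
    literal atom spheres (static) with the main-chain atoms.
    """
    if 360.0 % step != 0:
        raise ValueError(f"step {step} must divide 360")
    if residue.rotatable and residue.axis is None:
        raise ValueError(f"residue {residue.key} flagged rotatable but has no axis")

    main_spheres = [a.sphere for a in residue.main_chain]
    if not residue.rotatable:
        rot = Rotamer(
            residue_key=residue.key, index=0, angle=0.0, atoms=residue.side_chain
        )
        bound_parts = main_spheres + [a.sphere for a in residue.side_chain]
        bsv = enclosing_sphere(bound_parts) if bound_parts else Sphere(
            np.zeros(3), 0.0
        )
        return RotamerSet(residue_key=residue.key, rotamers=(rot,), bsv=bsv)

    n_rot = int(round(360.0 / step))
    coords = np.array([a.center for a in residue.side_chain])
    rotamers = []
    for j in range(n_rot):
        angle = j * step
        if j == 0:
            new_coords = coords
        else:
            new_coords = rotate_points_about_axis(coords, residue.axis, angle)
        atoms = tuple(
            AtomSphere(
                serial=a.serial,
                name=a.name,
                element=a.element,
                center=c,
                radius=a.radius,
                residue_key=a.residue_key,
            )
            for a, c in zip(residue.side_chain, new_coords)
        )
        rotamers.append(
            Rotamer(residue_key=residue.key, index=j, angle=angle, atoms=atoms)
        )
    swept = [swept_bound(a.sphere, residue.axis) for a in residue.side_chain]
    bsv = enclosing_sphere(main_spheres + swept)
    return RotamerSet(residue_key=residue.key, rotamers=tuple(rotamers), bsv=bsv)


def rotamers_collide(a: Rotamer, b: Rotamer, tol: float = DEFAULT_TOL) -> bool:
    """True iff any atom of rotamer ``a`` overlaps any atom of ``b``.

    Only meaningful for rotamers of different residues (all such atom pairs
    are non-bonded).
    """
    ca, cb = a.coords(), b.coords()
    if len(ca) == 0 or len(cb) == 0:
        return False
    d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=2)
    rsum = a.radii()[:, None] + b.radii()[None, :]
    return bool(np.any(d2 < rsum * rsum - tol))


def _collides_static(
    rotamer: Rotamer,
    own_key: ResidueKey,
    static_atoms: list[tuple[AtomSphere, bool]],
    tol: float,
) -> AtomSphere | None:
    """First static atom the rotamer collides with, or None.

    ``static_atoms`` entries are (atom, is_own_main_chain); own-main-chain
    pairs listed in BONDED_EXCLUSIONS are skipped.
    """
    for ratom in rotamer.atoms:
        for satom, own_main in static_atoms:
            if own_main and (ratom.name, satom.name) in BONDED_EXCLUSIONS:
                continue
            d = ratom.center - satom.center
            rsum = ratom.radius + satom.radius
            if float(d @ d) < rsum * rsum - tol:
                return satom
    return None


def remove_invalid_rotamers(
    adjacent: AdjacentSet,
    molecule: Molecule,
    tol: float = DEFAULT_TOL,
    self_main_chain: bool = True,
) -> AdjacentSet:
    """Drop rotamers that collide with the static environment.

    Case 1: collision with any residue's main chain (including the
    rotamer's own, minus the forced bonded contacts near Cβ, unless
    ``self_main_chain`` is disabled).
    Case 2: collision with any atom of a residue outside the adjacent set,
    or with a hetero obstacle.

    Neither case can occur in a physically sane input pose, so an offending
    rotamer is simply removed.  A residue losing every rotamer raises
    :class:`AllRotamersInvalidError`.
    """
    in_s = set(adjacent.residues)
    # (atom, belongs-to-key) pairs of everything static
    statics: list[tuple[AtomSphere, ResidueKey | None]] = []
    for res in molecule.residues:
        for a in res.main_chain:
            statics.append((a, res.key))
        if res.key not in in_s:
            for a in res.side_chain:
                statics.append((a, None))
    for a in molecule.hetero_atoms:
        statics.append((a, None))

    new_sets = {}
    for key in adjacent.residues:
        rs = adjacent.rotamer_sets[key]
        relevant = []
        for atom, owner in statics:
            if owner == key:
                if not self_main_chain:
                    continue
                relevant.append((atom, True))
            else:
                relevant.append((atom, False))
        survivors = []
        for rot in rs.rotamers:
            hit = _collides_static(rot, key, relevant, tol)
            if hit is None:
                survivors.append(rot)
            else:
                logger.debug(
                    "pruned rotamer %s.R%d: collides with %s of %s",
                    key, rot.index, hit.name, hit.residue_key,
                )
        if not survivors:
            raise AllRotamersInvalidError(
                f"residue {key}: every rotamer collides with the static "
                "environment"
            )
        new_sets[key] = RotamerSet(
            residue_key=key, rotamers=tuple(survivors), bsv=rs.bsv
        )
    return AdjacentSet(residues=adjacent.residues, rotamer_sets=new_sets)


# ---------------------------------------------------------------------------
# analytic counts for the discretization


def candidate_space(n_residues: int, rotamers_per_residue: int = 12) -> int:
    """Size of the unpruned conformation candidate space: k^n.

    With the default 30° single-axis grid each residue has 12 rotamers, so
    n tunnel-adjacent residues span 12^n candidates.
    """
    return rotamers_per_residue ** n_residues


def staggered_conformation_count(n_axes: int = 4, per_axis: int = 3) -> int:
    """Conformation count of the full multi-axis rotamer tree: 3^axes.

    Tetrahedral carbons favor staggered arrangements, i.e. three rotamers
    per rotation axis; a long side chain with four axes spans 3^4 = 81
    conformations.  The single-axis 30° grid above is the coarse stand-in
    this package actually enumerates.
    """
    return per_axis ** n_axes
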