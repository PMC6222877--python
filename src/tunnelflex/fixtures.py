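"""Deterministic synthetic inputs: the three-residue worked example and
seeded random toy molecules around a curved tunnel.

The worked example exists in two forms.  The *abstract* form pins the
published collision relations directly as a pre-built collision-free graph
(three residues A2, A3, A5 with three rotamers each, two rotamers invalid,
exactly three colliding rotamer pairs among the survivors), so the graph and
combination stages can be tested without any geometry.  The *geometric* form
realizes the same relations with concrete sphere coordinates and a coarse
120° rotamer step, proving the full pipeline (parsing, rotamer generation,
pruning, graphs) reproduces them; its construction self-validates and raises
if the planted collision matrix is not realized.

Random toys place pseudo-residues — a four-atom main chain plus a short
side-chain arm with a genuine Cα–Cβ axis — alongside a curved tunnel
centerline.  They use an all-carbon 0.7 Å radius table: the toys' bond
lengths are protein-like, and at full Bondi radii any chemically bonded arm
overlaps its own backbone under the strict non-bonded collision rule, which
is exactly the regime these fixtures are not trying to model (physically
realistic packing is out of scope; planted, controllable collision structure
is the point).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .conformation_graphs import (
    AminoCollisionClique,
    CollisionFreeGraph,
    build_collision_graph,
    build_temporary_graph,
)
from .geometry import Sphere
from .model_io import (
    AtomSphere,
    Molecule,
    RadiusTable,
    Residue,
    ResidueKey,
    partition_residue,
)
from .rotamers import (
    AdjacentSet,
    Rotamer,
    RotamerSet,
    generate_rotamers,
    remove_invalid_rotamers,
    rotamers_collide,
)
from .tunnel import TunnelProfile, tunnel_adjacent_residues

#: Rotamer step used by the geometric worked example (3 rotamers/residue).
WORKED_EXAMPLE_STEP = 120.0

#: Radius table for toy fixtures (all-carbon pseudo-residues).
TOY_RADII = RadiusTable(radii={"C": 0.7}, name="toy")

_A2: ResidueKey = ("A", 2, "")
_A3: ResidueKey = ("A", 3, "")
_A5: ResidueKey = ("A", 5, "")


@dataclass(frozen=True)
class WorkedExample:
    """The published three-residue example in abstract-graph form."""

    adjacent: AdjacentSet
    clique: AminoCollisionClique
    fg: CollisionFreeGraph
    surviving: dict
    colliding_pairs: frozenset
    invalid_rotamers: frozenset


def worked_example_graph() -> WorkedExample:
    """The worked example as pre-built graph structures (no geometry).

    Three residues with rotamers {R0, R1, R2}; A2.R0 and A3.R2 are invalid;
    the surviving colliding pairs are exactly (A2.R2, A3.R0),
    (A2.R2, A5.R1) and (A3.R1, A5.R0).
    """
    surviving = {_A2: [1, 2], _A3: [0, 1], _A5: [0, 1, 2]}
    colliding = frozenset(
        {
            frozenset(((_A2, 2), (_A3, 0))),
            frozenset(((_A2, 2), (_A5, 1))),
            frozenset(((_A3, 1), (_A5, 0))),
        }
    )
    sets = {}
    for key, indices in surviving.items():
        rots = tuple(
            Rotamer(residue_key=key, index=j, angle=j * 120.0, atoms=())
            for j in indices
        )
        sets[key] = RotamerSet(
            residue_key=key, rotamers=rots, bsv=Sphere(np.zeros(3), 1.0)
        )
    adjacent = AdjacentSet(residues=(_A2, _A3, _A5), rotamer_sets=sets)
    clique = AminoCollisionClique(index=0, members=frozenset((_A2, _A3, _A5)))

    vertices = {
        (key, j) for key, indices in surviving.items() for j in indices
    }
    keys = [_A2, _A3, _A5]
    edges = set()
    for i in range(3):
        for j in range(i + 1, 3):
            for a in surviving[keys[i]]:
                for b in surviving[keys[j]]:
                    e = frozenset(((keys[i], a), (keys[j], b)))
                    if e not in colliding:
                        edges.add(e)
    fg = CollisionFreeGraph(
        clique_index=0, vertices=frozenset(vertices), edges=frozenset(edges)
    )
    return WorkedExample(
        adjacent=adjacent,
        clique=clique,
        fg=fg,
        surviving=surviving,
        colliding_pairs=colliding,
        invalid_rotamers=frozenset(((_A2, 0), (_A3, 2))),
    )


def _residue(
    key: ResidueKey,
    rtype: str,
    named_coords: dict,
    radius: float,
    serial_start: int,
) -> Residue:
    atoms = []
    for i, (name, xyz) in enumerate(named_coords.items()):
        atoms.append(
            AtomSphere(
                serial=serial_start + i,
                name=name,
                element="C",
                center=np.asarray(xyz, dtype=float),
                radius=radius,
                residue_key=key,
            )
        )
    return partition_residue(atoms, rtype)


def worked_example_geometry() -> tuple[Molecule, TunnelProfile]:
    """Concrete coordinates realizing the worked example's relations.

    Three rotatable residues (vertical Cα–Cβ axes, one rotating arm tip on a
    circle, 120° step → rotamers R0..R2) plus two static glycines planted to
    invalidate A2.R0 and A3.R2.  Atom radius is 0.3 Å so planted tip–tip
    contacts at ~0.4 Å collide while the designed ≥0.75 Å separations do
    not.  Construction is validated on the spot: the function re-runs
    adjacency + pruning and asserts the planted collision matrix.
    """
    r = 0.3

    def rot120(v: np.ndarray) -> np.ndarray:
        c, s = math.cos(2 * math.pi / 3), math.sin(2 * math.pi / 3)
        return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])

    # Rotating arm tips: residue i's rotamer j tip is C_i + R(120 j)(v_i).
    c2, v2 = np.array([3.0, 0.0]), np.array([1.5, -2.598])  # T2,0=(4.5,-2.598)
    c3, v3 = np.array([0.4, 3.1]), np.array([0.0, -3.0])  # T3,0=(0.4, 0.1)
    # A5 is solved so that T5,0 sits 0.4 from T3,1 and T5,1 sits 0.4 from
    # T2,2=(0,0): v = (R - I)^-1 (T5,1 - T5,0), C5 = T5,0 - v.
    t50 = np.array([3.398, 4.6])
    t51 = np.array([-0.4, 0.0])
    cth, sth = math.cos(2 * math.pi / 3), math.sin(2 * math.pi / 3)
    rm = np.array([[cth, -sth], [sth, cth]])
    v5 = np.linalg.solve(rm - np.eye(2), t51 - t50)
    c5 = t50 - v5

    def rotatable(cxy, tip0, cb_z):
        cx, cy = float(cxy[0]), float(cxy[1])
        return {
            "N": (cx - 0.5, cy, 0.0),
            "CA": (cx, cy, 0.0),
            "C": (cx + 0.5, cy, 0.0),
            "O": (cx + 0.8, cy, -0.4),
            "CB": (cx, cy, cb_z),
            "CG": (float(tip0[0]), float(tip0[1]), 1.0),
        }

    def static_gly(key_xy, z):
        x, y = key_xy
        return {
            "CA": (x, y, z),
            "N": (x - 0.5, y, 3.0),
            "C": (x + 0.5, y, 3.0),
            "O": (x + 0.8, y, 3.3),
        }

    residues = (
        _residue(("A", 1, ""), "GLY", static_gly((4.5, -2.598), 1.35), r, 1),
        _residue(_A2, "LEU", rotatable(c2, c2 + v2, 0.4), r, 11),
        _residue(_A3, "LEU", rotatable(c3, c3 + v3, 1.6), r, 21),
        _residue(("A", 4, ""), "GLY", static_gly((-2.198, 4.6), 1.35), r, 31),
        _residue(_A5, "LEU", rotatable(c5, t50, 0.4), r, 41),
    )
    molecule = Molecule(residues=residues)
    tunnel = TunnelProfile(
        t=np.array([0.0, 0.5, 1.0]),
        centers=np.array([[1.5, 1.5, -1.0], [1.5, 1.5, 0.0], [1.5, 1.5, 1.0]]),
        radii=np.array([1.0, 0.5, 1.0]),
    )

    _validate_worked_geometry(molecule, tunnel)
    return molecule, tunnel


def _validate_worked_geometry(molecule: Molecule, tunnel: TunnelProfile) -> None:
    """Assert the geometric fixture realizes the planted relations."""
    reference = worked_example_graph()
    rotamer_sets = {
        res.key: generate_rotamers(res, step=WORKED_EXAMPLE_STEP)
        for res in molecule.residues
    }
    adjacent = tunnel_adjacent_residues(molecule, rotamer_sets, tunnel)
    if set(adjacent.residues) != {_A2, _A3, _A5}:
        raise AssertionError(
            f"tunnel-adjacent set is {adjacent.residues}, expected A2/A3/A5"
        )
    pruned = remove_invalid_rotamers(adjacent, molecule)
    surviving = {
        key: pruned.rotamer_sets[key].indices for key in pruned.residues
    }
    if surviving != reference.surviving:
        raise AssertionError(
            f"pruning produced {surviving}, expected {reference.surviving}"
        )
    observed = set()
    keys = list(pruned.residues)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            for x in pruned.rotamer_sets[keys[i]].rotamers:
                for y in pruned.rotamer_sets[keys[j]].rotamers:
                    if rotamers_collide(x, y):
                        observed.add(
                            frozenset(
                                ((keys[i], x.index), (keys[j], y.index))
                            )
                        )
    if observed != set(reference.colliding_pairs):
        raise AssertionError(
            f"collision matrix {observed} differs from the planted relations"
        )
    # the input tunnel must be collision-free against the input pose
    atoms = [a for res in molecule.residues for a in res.atoms]
    for c, r in zip(tunnel.centers, tunnel.radii):
        clearance = min(
            float(np.linalg.norm(a.center - c)) - a.radius for a in atoms
        )
        if clearance < r:
            raise AssertionError(
                f"tunnel ball at {c} (r={r}) overlaps an input-pose atom"
            )


# ---------------------------------------------------------------------------
# random toys


@dataclass(frozen=True)
class ToySpec:
    """Parameters of a random toy molecule + tunnel.

    ``packing`` in [0, 1] controls how tightly residues crowd the
    centerline (0 → BSVs pairwise disjoint, 1 → dense overlap);
    ``atoms_per_side_chain`` counts arm atoms including Cβ.
    """

    n_residues: int = 4
    atoms_per_side_chain: int = 2
    packing: float = 0.5
    seed: int = 0
    tunnel_samples: int = 8

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.atoms_per_side_chain < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.packing <= 1.0:
            raise ValueError("packing must lie in [0, 1]")
        if self.tunnel_samples < 2:
            raise ValueError("a tunnel needs at least 2 samples")


_ARM_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH", "CI", "CK"]


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _toy_once(spec: ToySpec, rng: np.random.Generator) -> tuple[Molecule, TunnelProfile]:
    n = spec.n_residues
    m = spec.atoms_per_side_chain
    radius = TOY_RADII["C"]

    # residue spacing: from pairwise-disjoint BSVs down to heavy overlap
    far = 9.0 + 1.6 * m
    near = 2.5
    spacing = near + (far - near) * (1.0 - spec.packing)
    length = spacing * max(n - 1, 1)

    def centerline(u: float) -> np.ndarray:
        x = length * u
        return np.array([x, 0.015 * x * x, 0.1 * x])

    def tangent(u: float) -> np.ndarray:
        d = centerline(min(u + 1e-4, 1.0)) - centerline(max(u - 1e-4, 0.0))
        return d / np.linalg.norm(d)

    residues = []
    serial = 1
    for i in range(n):
        u = i / max(n - 1, 1)
        base = centerline(u)
        tang = tangent(u)
        # lateral offset keeps the centerline itself clear of backbones
        perp = np.cross(tang, _unit(rng))
        perp /= np.linalg.norm(perp)
        ca = base + perp * rng.uniform(1.3, 2.0)
        w1 = _unit(rng)
        w2 = _unit(rng)
        axis_dir = _unit(rng)
        coords = {
            "N": ca + 0.5 * w1,
            "CA": ca,
            "C": ca - 0.5 * w1,
            "O": ca - 0.5 * w1 + 0.4 * w2,
        }
        pos = ca + 1.5 * axis_dir
        coords["CB"] = pos
        prev_dir = axis_dir
        for k in range(1, m):
            bend = np.cross(prev_dir, _unit(rng))
            nb = np.linalg.norm(bend)
            bend = bend / nb if nb > 1e-9 else _unit(rng)
            d = 0.55 * prev_dir + 0.84 * bend  # ~57° bend, protein-like
            d /= np.linalg.norm(d)
            pos = pos + 1.4 * d
            coords[_ARM_NAMES[k]] = pos
            prev_dir = d
        named = {
            name: tuple(np.round(xyz, 3)) for name, xyz in coords.items()
        }
        residues.append(
            _residue(("A", i + 1, ""), "LEU", named, radius, serial)
        )
        serial += len(named)

    molecule = Molecule(residues=tuple(residues))

    # tunnel: samples along the centerline; radii drawn, then clamped under
    # the input-pose clearance so the initial tunnel is collision-free
    ts = np.linspace(0.0, 1.0, spec.tunnel_samples)
    centers = np.array([centerline(u) for u in ts])
    desired = rng.uniform(0.6, 1.2, size=spec.tunnel_samples)
    all_atoms = [a for res in molecule.residues for a in res.atoms]
    ac = np.array([a.center for a in all_atoms])
    ar = np.array([a.radius for a in all_atoms])
    radii = np.empty_like(desired)
    for k, c in enumerate(centers):
        clearance = float((np.linalg.norm(ac - c, axis=1) - ar).min())
        radii[k] = min(desired[k], max(0.95 * clearance, 1e-3))
    radii = np.round(radii, 3)
    tunnel = TunnelProfile(t=ts, centers=centers, radii=radii)
    return molecule, tunnel


def random_toy(spec: ToySpec, max_retries: int = 30) -> tuple[Molecule, TunnelProfile]:
    """Seeded toy molecule + tunnel with a usable rotamer structure.

    Re-draws (bounded) when a placement leaves some residue with no valid
    rotamer at the default 30° step, so downstream stages always have a
    non-degenerate adjacent set to work with.  Same spec → identical output.
    """
    rng = np.random.default_rng(spec.seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        molecule, tunnel = _toy_once(spec, rng)
        try:
            rotamer_sets = {
                res.key: generate_rotamers(res, step=30.0)
                for res in molecule.residues
            }
            adjacent = tunnel_adjacent_residues(molecule, rotamer_sets, tunnel)
            remove_invalid_rotamers(adjacent, molecule)
        except ValueError as err:
            last_err = err
            continue
        return molecule, tunnel
    raise RuntimeError(
        f"could not realize toy spec {spec} in {max_retries} draws"
    ) from last_err


# ---------------------------------------------------------------------------
# file emission (exercises the I/O paths)


def _pdb_atom_line(a: AtomSphere, res_type: str) -> str:
    chain, num, icode = a.residue_key
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {a.serial:5d} {name:4s} {res_type:>3s} {chain:1s}"
        f"{num:4d}{icode or ' ':1s}   "
        f"{a.center[0]:8.3f}{a.center[1]:8.3f}{a.center[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
    )


def write_toy_files(spec: ToySpec, outdir: str | Path) -> dict:
    """Emit molecule.pdb, tunnel.tsv and provenance.json for a toy spec."""
    from .model_io import write_tunnel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    molecule, tunnel = random_toy(spec)
    lines = []
    for res in molecule.residues:
        for a in sorted(res.atoms, key=lambda x: x.serial):
            lines.append(_pdb_atom_line(a, res.type))
    lines.append("END")
    (outdir / "molecule.pdb").write_text("\n".join(lines) + "\n")
    write_tunnel(tunnel, outdir / "tunnel.tsv")
    prov = {"generator": "tunnelflex.fixtures.random_toy", **asdict(spec)}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1))
    return prov
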