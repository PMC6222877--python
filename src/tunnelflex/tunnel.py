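"""Swept-ball tunnel model, bottleneck detection, and clearance recomputation.

A tunnel (or channel) is modeled as an empty ball swept along a centerline:
an ordered sequence of samples ``(t, center, radius)`` with ``t`` strictly
increasing in [0, 1].  A *bottleneck* is a sample whose radius is a discrete
strict local minimum; the minimum bottleneck limits the largest spherical
ligand that can pass.

``recompute_tunnel`` produces the deformed tunnel for a given side-chain
conformation by keeping the centerline fixed and re-measuring the clearance
radius at each sample — the distance from the sample center to the nearest
obstacle sphere surface.  This keeps the bottleneck semantics on the same
path; tunnel re-routing (entrance relocation) is deliberately out of scope,
and the step is isolated so a full tunnel finder can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .geometry import DEFAULT_TOL, Sphere

if TYPE_CHECKING:  # pragma: no cover
    from .model_io import Molecule
    from .rotamers import AdjacentSet, RotamerSet


@dataclass(frozen=True)
class TunnelProfile:
    """Ordered swept-ball samples of a tunnel.

    Attributes
    ----------
    t : (n,) float array, strictly increasing, in [0, 1]
    centers : (n, 3) float array, Å
    radii : (n,) float array, Å, all > 0
    """

    t: np.ndarray
    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        radii = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)
        if len(t) < 2:
            raise ValueError("a tunnel profile needs at least 2 samples")
        if not (len(t) == len(centers) == len(radii)):
            raise ValueError("t, centers, radii must have equal lengths")
        if np.any(np.diff(t) <= 0):
            raise ValueError("tunnel parameter t must be strictly increasing")
        if np.any(radii <= 0):
            raise ValueError("tunnel radii must be positive")

    def __len__(self) -> int:
        return len(self.t)

    def sample_spheres(self) -> list[Sphere]:
        return [Sphere(c, float(r)) for c, r in zip(self.centers, self.radii)]

    def with_radii(self, radii: Sequence[float]) -> "TunnelProfile":
        """Same centerline, new radii (used by clearance recomputation)."""
        r = np.asarray(radii, dtype=float)
        # Bypass the positivity check: a recomputed clearance may be 0
        # (fully blocked tunnel), which is meaningful output.
        obj = object.__new__(TunnelProfile)
        object.__setattr__(obj, "t", self.t.copy())
        object.__setattr__(obj, "centers", self.centers.copy())
        object.__setattr__(obj, "radii", r)
        return obj


@dataclass(frozen=True)
class Bottleneck:
    """A discrete strict local minimum of the tunnel radius profile."""

    sample_index: int
    t: float
    radius: float


def find_bottlenecks(tunnel: TunnelProfile) -> list[Bottleneck]:
    """All interior strict local minima of the radius profile.

    A plateau of equal minimal radii flanked on both sides by strictly larger
    radii counts once, reported at the plateau's first sample.  Endpoints are
    never bottlenecks.
    """
    r = tunnel.radii
    n = len(r)
    out: list[Bottleneck] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and r[j + 1] == r[i]:
            j += 1
        # run [i, j] of equal radii; interior iff it excludes both endpoints
        if i > 0 and j < n - 1 and r[i - 1] > r[i] and r[j + 1] > r[i]:
            out.append(Bottleneck(i, float(tunnel.t[i]), float(r[i])))
        i = j + 1
    return out


def min_bottleneck_radius(tunnel: TunnelProfile) -> float:
    """Minimum bottleneck radius; falls back to the global minimum radius.

    A monotone profile has no interior local minimum, yet its narrowest
    sample still limits the passable ligand size, hence the fallback.
    """
    bns = find_bottlenecks(tunnel)
    if bns:
        return min(b.radius for b in bns)
    return float(tunnel.radii.min())


def tunnel_adjacent_residues(
    molecule: "Molecule",
    rotamer_sets: dict,
    tunnel: TunnelProfile,
    tol: float = DEFAULT_TOL,
) -> "AdjacentSet":
    """Select the residues whose BSV intersects at least one tunnel ball.

    Because a residue's BSV spans every rotamer, this covers both residues
    touching the tunnel in the given pose and residues that only a rotated
    side chain could swing into the tunnel.  Tangency counts as adjacency.
    """
    from .rotamers import AdjacentSet  # deferred: avoids an import cycle

    selected: list = []
    sets = {}
    for res in molecule.residues:
        rs = rotamer_sets[res.key]
        bsv = rs.bsv
        d2 = np.sum((tunnel.centers - bsv.center) ** 2, axis=1)
        rsum = tunnel.radii + bsv.radius
        if np.any(d2 <= rsum * rsum + tol):
            selected.append(res.key)
            sets[res.key] = rs
    if not selected:
        raise ValueError("tunnel touches no residue (empty adjacent set)")
    return AdjacentSet(residues=tuple(selected), rotamer_sets=sets)


def _static_obstacles(
    adjacent: "AdjacentSet", molecule: "Molecule"
) -> tuple[np.ndarray, np.ndarray]:
    """Centers/radii of every atom that never moves: all main chains, every
    atom of residues outside the adjacent set, and hetero obstacles."""
    centers: list[np.ndarray] = []
    radii: list[float] = []
    in_s = set(adjacent.residues)
    for res in molecule.residues:
        for a in res.main_chain:
            centers.append(a.center)
            radii.append(a.radius)
        if res.key not in in_s:
            for a in res.side_chain:
                centers.append(a.center)
                radii.append(a.radius)
    for a in molecule.hetero_atoms:
        centers.append(a.center)
        radii.append(a.radius)
    if centers:
        return np.array(centers), np.array(radii)
    return np.zeros((0, 3)), np.zeros((0,))


def recompute_tunnel(
    tunnel: TunnelProfile,
    conformation: Sequence[int],
    adjacent: "AdjacentSet",
    molecule: "Molecule",
    r_cap: float | None = None,
) -> TunnelProfile:
    """Clearance radii along the fixed centerline for one conformation.

    Each sample radius becomes ``min over atoms (|center - atom| - r_atom)``
    over all static atoms plus the side-chain atoms of the selected rotamers,
    clamped to ``[0, r_cap]``.  ``r_cap`` defaults to twice the original
    maximum radius so that samples with no nearby obstacle stay comparable
    across conformations.
    """
    conf = np.asarray(conformation, dtype=int)
    if conf.shape != (adjacent.n,):
        raise ValueError("conformation length does not match adjacent set")
    if np.any(conf < 0):
        raise ValueError("conformation has unassigned (-1) entries")
    if r_cap is None:
        r_cap = 2.0 * float(tunnel.radii.max())

    centers, radii = _static_obstacles(adjacent, molecule)
    parts_c = [centers]
    parts_r = [radii]
    for i, key in enumerate(adjacent.residues):
        rot = adjacent.rotamer_sets[key].by_index(int(conf[i]))
        if rot.atoms:
            parts_c.append(np.array([a.center for a in rot.atoms]))
            parts_r.append(np.array([a.radius for a in rot.atoms]))
    all_c = np.vstack(parts_c)
    all_r = np.concatenate(parts_r)

    new_radii = np.empty(len(tunnel))
    for s, c in enumerate(tunnel.centers):
        if len(all_c) == 0:
            new_radii[s] = r_cap
            continue
        clearance = np.linalg.norm(all_c - c, axis=1) - all_r
        new_radii[s] = min(max(float(clearance.min()), 0.0), r_cap)
    return tunnel.with_radii(new_radii)
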