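"""Sphere and rotation primitives.

Everything downstream — rotamer generation, bounding-sphere volumes (BSVs),
tunnel clearance — reduces to three operations on spheres: the strict
overlap test for a collision between non-bonded atoms, rigid rotation of a
point about the Cα–Cβ axis, and conservative enclosing spheres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Default slack subtracted from the squared radius sum so that floating-point
#: tangency can never register as a collision (the overlap test is strict).
DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class Sphere:
    """A ball in 3-space: ``center`` (Å) and ``radius`` (Å, >= 0)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("sphere center must be a 3-vector")
        if self.radius < 0:
            raise ValueError("sphere radius must be non-negative")


@dataclass(frozen=True)
class Axis:
    """A rotation axis through two distinct points (Cα and Cβ centers)."""

    point_a: np.ndarray
    point_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.point_a, dtype=float)
        b = np.asarray(self.point_b, dtype=float)
        object.__setattr__(self, "point_a", a)
        object.__setattr__(self, "point_b", b)
        if np.linalg.norm(b - a) == 0.0:
            raise ValueError("degenerate axis: the two points coincide")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from ``point_a`` to ``point_b``."""
        d = self.point_b - self.point_a
        return d / np.linalg.norm(d)


def spheres_collide(s1: Sphere, s2: Sphere, tol: float = DEFAULT_TOL) -> bool:
    """Strict sphere-overlap test.

    Two spheres collide iff the squared center distance is strictly below
    ``(r1 + r2)**2 - tol``; tangent spheres do NOT collide.  ``tol`` guards
    against floating-point noise flipping a tangency into an overlap.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    d2 = float(np.dot(s1.center - s2.center, s1.center - s2.center))
    rsum = s1.radius + s2.radius
    return d2 < rsum * rsum - tol


def spheres_touch(s1: Sphere, s2: Sphere, tol: float = DEFAULT_TOL) -> bool:
    """Inclusive overlap test (intersection is non-empty, tangency counts).

    Used for tunnel adjacency, where a BSV merely touching a tunnel ball
    already makes the residue relevant.
    """
    d2 = float(np.dot(s1.center - s2.center, s1.center - s2.center))
    rsum = s1.radius + s2.radius
    return d2 <= rsum * rsum + tol


def rotate_about_axis(p: np.ndarray, axis: Axis, angle_deg: float) -> np.ndarray:
    """Rotate point ``p`` about ``axis`` by ``angle_deg`` degrees.

    Right-handed about the unit vector from ``axis.point_a`` to
    ``axis.point_b`` (Rodrigues' formula).
    """
    p = np.asarray(p, dtype=float)
    k = axis.direction
    theta = math.radians(angle_deg)
    v = p - axis.point_a
    rotated = (
        v * math.cos(theta)
        + np.cross(k, v) * math.sin(theta)
        + k * np.dot(k, v) * (1.0 - math.cos(theta))
    )
    return axis.point_a + rotated


def rotate_points_about_axis(
    points: np.ndarray, axis: Axis, angle_deg: float
) -> np.ndarray:
    """Vectorized :func:`rotate_about_axis` for an (n, 3) array."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    k = axis.direction
    theta = math.radians(angle_deg)
    v = pts - axis.point_a
    rotated = (
        v * math.cos(theta)
        + np.cross(np.broadcast_to(k, v.shape), v) * math.sin(theta)
        + np.outer(v @ k, k) * (1.0 - math.cos(theta))
    )
    return axis.point_a + rotated


def point_line_distance(p: np.ndarray, axis: Axis) -> float:
    """Orthogonal distance from ``p`` to the infinite line through ``axis``."""
    p = np.asarray(p, dtype=float)
    k = axis.direction
    v = p - axis.point_a
    return float(np.linalg.norm(v - np.dot(v, k) * k))


def swept_bound(atom: Sphere, axis: Axis) -> Sphere:
    """Smallest axis-centered sphere containing the atom at every rotation.

    The swept volume of a sphere rotating about a line is a torus-like solid;
    the ball centered at the orthogonal projection of the atom center onto the
    axis, with radius distance-to-axis + atom radius, contains it for every
    angle.
    """
    k = axis.direction
    v = atom.center - axis.point_a
    along = np.dot(v, k)
    proj = axis.point_a + along * k
    dist = float(np.linalg.norm(atom.center - proj))
    return Sphere(center=proj, radius=dist + atom.radius)


def enclosing_sphere(spheres: Sequence[Sphere] | Iterable[Sphere]) -> Sphere:
    """A sphere containing every input sphere (near-minimal, deterministic).

    Ritter-style two-pass construction generalized to spheres: start from the
    centroid-farthest pair of sphere surfaces, then grow to swallow any sphere
    still outside.  The result is conservative — at most a few percent larger
    than the true minimal enclosing sphere — which is sound here because an
    oversized BSV only triggers extra exact pair checks, never a missed
    collision.
    """
    spheres = list(spheres)
    if not spheres:
        raise ValueError("enclosing_sphere requires a non-empty sphere list")
    if len(spheres) == 1:
        return spheres[0]

    centers = np.array([s.center for s in spheres])
    radii = np.array([s.radius for s in spheres])

    # Pass 0: seed at the sphere whose surface reaches farthest from the
    # centroid, then the surface farthest from that one.
    centroid = centers.mean(axis=0)
    d = np.linalg.norm(centers - centroid, axis=1) + radii
    i = int(np.argmax(d))
    d_i = np.linalg.norm(centers - centers[i], axis=1) + radii
    j = int(np.argmax(d_i))

    # Initial guess spanning spheres i and j.
    vij = centers[j] - centers[i]
    nij = float(np.linalg.norm(vij))
    if nij == 0.0:
        center = centers[i].copy()
        radius = float(max(radii[i], radii[j]))
    else:
        u = vij / nij
        lo = -radii[i]
        hi = nij + radii[j]
        center = centers[i] + u * (lo + hi) / 2.0
        radius = (hi - lo) / 2.0

    # Growth pass: expand minimally toward any sphere still sticking out.
    for _ in range(2):  # two sweeps suffice for near-minimality in practice
        for c, r in zip(centers, radii):
            gap = float(np.linalg.norm(c - center)) + r - radius
            if gap > 0.0:
                dvec = c - center
                dn = float(np.linalg.norm(dvec))
                radius += gap / 2.0
                if dn > 0.0:
                    center = center + dvec / dn * (gap / 2.0)
    # Final tightening guard: exact containment.
    need = np.linalg.norm(centers - center, axis=1) + radii
    radius = float(max(radius, need.max()))
    return Sphere(center=center, radius=radius)
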