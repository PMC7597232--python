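"""Cube orientation group, lattice directions, and the four-molecule cluster topology.

A die on a simple cubic lattice exposes six faces along the lattice axes.
Its orientation is one of the 24 proper rotations of the cube, represented
here as a permutation of the six axis directions: ``face_map`` sends a
body-frame direction (where a face sits on the die itself) to the lab-frame
direction it points at on the lattice.  Reflections are excluded — a die
cannot be mirrored by rigid motion.

Directions are indexed ``+x=0, -x=1, +y=2, -y=3, +z=4, -z=5`` so that
negation is ``index ^ 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

import numpy as np

__all__ = [
    "Direction",
    "DIRECTIONS",
    "PX", "NX", "PY", "NY", "PZ", "NZ",
    "Orientation",
    "ClusterTopology",
    "CLUSTER_TOPOLOGY",
    "enumerate_orientations",
    "identity_orientation",
    "compose",
    "inverse",
    "contact_faces",
    "axis_cycle_rotation",
]

# direction indices
PX, NX, PY, NY, PZ, NZ = range(6)

_AXIS_NAMES = ("x", "x", "y", "y", "z", "z")
_SIGNS = (1, -1, 1, -1, 1, -1)


@dataclass(frozen=True, order=True)
class Direction:
    """One of the six lattice directions (an axis and a sign)."""

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index < 6:
            raise ValueError(f"direction index out of range: {self.index}")

    @property
    def axis(self) -> str:
        return _AXIS_NAMES[self.index]

    @property
    def sign(self) -> int:
        return _SIGNS[self.index]

    def __neg__(self) -> "Direction":
        return Direction(self.index ^ 1)

    def __repr__(self) -> str:
        return f"{'+' if self.sign > 0 else '-'}{self.axis}"


DIRECTIONS: tuple[Direction, ...] = tuple(Direction(i) for i in range(6))


def _check_proper(perm: tuple[int, ...]) -> None:
    """Validate that a face permutation is a proper rotation of the cube."""
    if sorted(perm) != list(range(6)):
        raise ValueError(f"not a permutation of the six directions: {perm}")
    for d in range(6):
        if perm[d ^ 1] != perm[d] ^ 1:
            raise ValueError(f"opposite-face pairing broken at {d}: {perm}")
    # handedness: the images of +x, +y, +z must form a right-handed triad
    vecs = {PX: (1, 0, 0), NX: (-1, 0, 0), PY: (0, 1, 0),
            NY: (0, -1, 0), PZ: (0, 0, 1), NZ: (0, 0, -1)}
    ex, ey, ez = vecs[perm[PX]], vecs[perm[PY]], vecs[perm[PZ]]
    det = (ex[0] * (ey[1] * ez[2] - ey[2] * ez[1])
           - ex[1] * (ey[0] * ez[2] - ey[2] * ez[0])
           + ex[2] * (ey[0] * ez[1] - ey[1] * ez[0]))
    if det != 1:
        raise ValueError(f"improper rotation (det={det}): {perm}")


@dataclass(frozen=True)
class Orientation:
    """A proper rotation of the cube as a permutation of the six directions.

    ``perm[body_index] = lab_index``: the body-frame face ``body_index``
    points along lab direction ``perm[body_index]``.
    """

    id: int
    perm: tuple[int, ...]

    def __post_init__(self) -> None:
        _check_proper(self.perm)

    @property
    def inv_perm(self) -> tuple[int, ...]:
        inv = [0] * 6
        for b, l in enumerate(self.perm):
            inv[l] = b
        return tuple(inv)

    def face_map(self, body: Direction) -> Direction:
        """Lab-frame direction that body-frame face ``body`` points along."""
        return Direction(self.perm[body.index])

    def body_face_along(self, lab: Direction) -> Direction:
        """Body-frame face that points along lab direction ``lab``."""
        return Direction(self.inv_perm[lab.index])

    def __repr__(self) -> str:
        return f"Orientation(id={self.id})"


def _compose_perm(p1: tuple[int, ...], p2: tuple[int, ...]) -> tuple[int, ...]:
    # apply p2 first, then p1
    return tuple(p1[p2[d]] for d in range(6))


# generators: 90-degree rotations about z (+x -> +y) and about x (+y -> +z)
_ROT_Z = (PY, NY, NX, PX, PZ, NZ)
_ROT_X = (PX, NX, PZ, NZ, NY, PY)
_IDENT = (PX, NX, PY, NY, PZ, NZ)


@lru_cache(maxsize=1)
def enumerate_orientations() -> tuple[Orientation, ...]:
    """All 24 proper rotations of the cube, in a fixed reproducible order.

    The set is generated breadth-first from the identity with the two
    90-degree generators (about z, then about x), so ids are stable across
    runs; id 0 is the identity.
    """
    seen: dict[tuple[int, ...], int] = {_IDENT: 0}
    order: list[tuple[int, ...]] = [_IDENT]
    frontier = [_IDENT]
    while frontier:
        new_frontier = []
        for p in frontier:
            for g in (_ROT_Z, _ROT_X):
                q = _compose_perm(g, p)
                if q not in seen:
                    seen[q] = len(order)
                    order.append(q)
                    new_frontier.append(q)
        frontier = new_frontier
    assert len(order) == 24
    return tuple(Orientation(i, p) for i, p in enumerate(order))


def identity_orientation() -> Orientation:
    return enumerate_orientations()[0]


@lru_cache(maxsize=1)
def _perm_to_id() -> dict[tuple[int, ...], int]:
    return {o.perm: o.id for o in enumerate_orientations()}


def orientation_from_perm(perm: tuple[int, ...]) -> Orientation:
    """Look up the canonical Orientation with the given face permutation."""
    try:
        return enumerate_orientations()[_perm_to_id()[tuple(perm)]]
    except KeyError:
        raise ValueError(f"not a proper cube rotation: {perm}") from None


def compose(o1: Orientation, o2: Orientation) -> Orientation:
    """Composition ``o1 ∘ o2`` (apply ``o2`` first, then ``o1``)."""
    return orientation_from_perm(_compose_perm(o1.perm, o2.perm))


def inverse(o: Orientation) -> Orientation:
    return orientation_from_perm(o.inv_perm)


def axis_cycle_rotation() -> Orientation:
    """The 120-degree rotation about the (1,1,1) diagonal: +x→+y→+z→+x.

    This is the rotation that cyclically permutes the three cluster bond
    axes and generates the three equivalent views of one cluster
    (lattice isotropy).
    """
    perm = (PY, NY, PZ, NZ, PX, NX)
    return orientation_from_perm(perm)


def contact_faces(
    orient_a: Orientation, orient_b: Orientation, bond: Direction
) -> tuple[Direction, Direction]:
    """Body-frame faces in contact across a bond from molecule A to B.

    ``bond`` points from A's site to B's site.  Returns the body-frame face
    of A that faces along ``bond`` in the lab frame, and the body-frame face
    of B that faces along ``-bond`` (back toward A).
    """
    return orient_a.body_face_along(bond), orient_b.body_face_along(-bond)


@dataclass(frozen=True)
class ClusterTopology:
    """The four-molecule cluster: central A with neighbors B, C, D.

    The neighbors sit on three mutually orthogonal bonds from A.  The sign
    convention (positive octant: +x, +y, +z) is immaterial by isotropy and
    fixed once here.
    """

    bonds: tuple[Direction, Direction, Direction]

    def __iter__(self) -> Iterator[Direction]:
        return iter(self.bonds)


CLUSTER_TOPOLOGY = ClusterTopology((Direction(PX), Direction(PY), Direction(PZ)))


def orientation_permutation_array() -> np.ndarray:
    """(24, 6) int array: row o gives perm of orientation o (body→lab)."""
    return np.array([o.perm for o in enumerate_orientations()], dtype=np.int64)
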