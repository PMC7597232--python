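"""Molecule specifications, interaction-energy tables, and interchange energy.

A molecule is a die whose six faces carry integer interaction-site classes.
Pairwise contact energies are dimensionless (per k_B·T per contact) and are
looked up by the ordered pair of touching face classes.  The interchange
energy ``omega_ij = eps_ij + eps_ji - eps_ii - eps_jj`` condenses a table
into a single net like/unlike preference: negative means unlike contacts are
favoured (net attraction).

Three built-in molecule types exercise the geometric capabilities of the
model: Angled (class-1 and class-2 faces sharing an edge), Stretched (the
same two classes on opposite faces) and Inert (all faces class 0).  Angled
and Stretched carry identical face-class multisets — they are isomers,
distinguishable only through geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .geometry import DIRECTIONS, Direction, NX, NY, NZ, PX, PY, PZ

__all__ = [
    "SiteClass",
    "MoleculeSpec",
    "InteractionTable",
    "builtin_molecule",
    "BUILTIN_NAMES",
    "interchange_energy",
    "table_from_interchange",
    "table1_pattern",
    "uniform_molecule",
]

#: Site classes are plain small non-negative integers; 0 is inert only
#: if the interaction table says so.
SiteClass = int


@dataclass(frozen=True)
class MoleculeSpec:
    """A component's six die faces labelled with interaction-site classes.

    ``face_classes[i]`` is the class of the body-frame face with direction
    index ``i`` (order +x, -x, +y, -y, +z, -z).
    """

    component_id: int
    face_classes: tuple[SiteClass, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.face_classes) != 6:
            raise ValueError("a molecule has exactly six faces")
        if any(c < 0 for c in self.face_classes):
            raise ValueError("site classes are non-negative integers")

    @classmethod
    def from_mapping(
        cls, component_id: int, faces: Mapping[Direction, SiteClass], name: str = ""
    ) -> "MoleculeSpec":
        if set(faces) != set(DIRECTIONS):
            raise ValueError("exactly one class per face is required")
        return cls(component_id, tuple(faces[d] for d in DIRECTIONS), name)

    def face_class(self, body: Direction) -> SiteClass:
        return self.face_classes[body.index]

    @property
    def classes(self) -> frozenset[SiteClass]:
        return frozenset(self.face_classes)

    @property
    def is_uniform(self) -> bool:
        return len(self.classes) == 1

    def with_component_id(self, component_id: int) -> "MoleculeSpec":
        return MoleculeSpec(component_id, self.face_classes, self.name)


class InteractionTable:
    """Pairwise contact energies eps_ij per k_B·T, by ordered class pair."""

    def __init__(self, eps: Mapping[tuple[SiteClass, SiteClass], float]):
        self._eps = {(int(i), int(j)): float(v) for (i, j), v in eps.items()}
        for (i, j), v in self._eps.items():
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"non-finite energy for pair ({i},{j})")

    def energy(self, i: SiteClass, j: SiteClass) -> float:
        try:
            return self._eps[(i, j)]
        except KeyError:
            raise KeyError(f"no interaction energy defined for classes ({i},{j})") from None

    def __contains__(self, pair: tuple[SiteClass, SiteClass]) -> bool:
        return tuple(pair) in self._eps

    @property
    def classes(self) -> frozenset[SiteClass]:
        return frozenset(i for pair in self._eps for i in pair)

    def items(self) -> Iterable[tuple[tuple[SiteClass, SiteClass], float]]:
        return self._eps.items()

    def scaled(self, factor: float) -> "InteractionTable":
        """Table with all entries multiplied by ``factor`` (a coupling or
        inverse-temperature scale)."""
        return InteractionTable({p: v * factor for p, v in self._eps.items()})

    def is_symmetric(self, tol: float = 0.0) -> bool:
        return all(
            abs(v - self._eps.get((j, i), float("nan"))) <= tol
            for (i, j), v in self._eps.items()
        )

    def __repr__(self) -> str:
        entries = ", ".join(f"({i},{j}): {v:g}" for (i, j), v in sorted(self._eps.items()))
        return f"InteractionTable({{{entries}}})"


def _angled_faces() -> tuple[int, ...]:
    faces = [0] * 6
    faces[PX] = 1
    faces[PY] = 2  # +x and +y share an edge
    return tuple(faces)


def _stretched_faces() -> tuple[int, ...]:
    faces = [0] * 6
    faces[PX] = 1
    faces[NX] = 2  # opposite faces
    return tuple(faces)


BUILTIN_NAMES = ("angled", "stretched", "inert")


def builtin_molecule(name: str, component_id: int = 1) -> MoleculeSpec:
    """One of the built-in molecule types: ``angled``, ``stretched``, ``inert``.

    Which particular face pair hosts classes 1 and 2 is arbitrary by lattice
    isotropy; the constants are fixed here (+x/+y for Angled, +x/-x for
    Stretched).
    """
    key = name.strip().lower()
    if key == "angled":
        return MoleculeSpec(component_id, _angled_faces(), "Angled")
    if key == "stretched":
        return MoleculeSpec(component_id, _stretched_faces(), "Stretched")
    if key == "inert":
        return MoleculeSpec(component_id, (0,) * 6, "Inert")
    raise ValueError(f"unknown built-in molecule {name!r}; choose from {BUILTIN_NAMES}")


def uniform_molecule(site_class: SiteClass, component_id: int = 1) -> MoleculeSpec:
    """A molecule with the same class on all six faces (sphere-like)."""
    return MoleculeSpec(component_id, (site_class,) * 6, f"Uniform{site_class}")


def interchange_energy(table: InteractionTable, i: SiteClass, j: SiteClass) -> float:
    """omega_ij = eps_ij + eps_ji - eps_ii - eps_jj (per k_B·T)."""
    return (
        table.energy(i, j) + table.energy(j, i)
        - table.energy(i, i) - table.energy(j, j)
    )


def table_from_interchange(omega: float) -> InteractionTable:
    """The symmetric like-repels/unlike-attracts pattern with a given omega_12.

    Classes 1 and 2 interact with eps_11 = eps_22 = -omega/4 and
    eps_12 = eps_21 = +omega/4, so the interchange energy is exactly
    ``omega``; any pair involving class 0 is inert (zero energy).
    """
    omega = float(omega)
    if not (omega == omega and abs(omega) != float("inf")):
        raise ValueError("omega must be finite")
    q = omega / 4.0
    eps: dict[tuple[int, int], float] = {}
    for i in (0, 1, 2):
        for j in (0, 1, 2):
            if i == 0 or j == 0:
                eps[(i, j)] = 0.0
            elif i == j:
                eps[(i, j)] = -q
            else:
                eps[(i, j)] = q
    return InteractionTable(eps)


def table1_pattern() -> InteractionTable:
    """The printed ±1200 like-repulsion / unlike-attraction pattern.

    Kept as a named fixture; sweeps use :func:`table_from_interchange`
    driven directly by the dimensionless interchange energy.
    """
    eps: dict[tuple[int, int], float] = {}
    for i in (0, 1, 2):
        for j in (0, 1, 2):
            if i == 0 or j == 0:
                eps[(i, j)] = 0.0
            elif i == j:
                eps[(i, j)] = 1200.0
            else:
                eps[(i, j)] = -1200.0
    return InteractionTable(eps)
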