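"""Cluster-state space, probability algebra, entropy and energy of the lattice model.

The model's unit is a four-molecule cluster: a central die A with neighbors
B, C, D along the +x, +y, +z bonds.  A molecule state is a (component,
orientation) pair — 2 x 24 = 48 states for a two-component dice system —
and a cluster state is a quadruple of molecule states, 48^4 = 5,308,416 in
the general case.

The sequential construction of the lattice (inserting a molecule into an
existing three-neighbor environment, a discrete Markov chain) makes the
system entropy per molecule the conditional Shannon entropy of the inserted
state given its neighborhood::

    S / (N k_B) = - sum_{abcd} p_abcd ln( p_abcd / p_bcd ),
    p_bcd = sum_a p_abcd

and the internal energy the probability-weighted mean of the additive
three-bond cluster energies.  The Helmholtz free energy per molecule is the
dimensionless combination A/(N k_B T) = U/(N k_B T) - S/(N k_B).

Two structural reductions keep the variable count manageable:

* isotropy — the three views of a cluster obtained by cyclically rotating
  the bond axes (a 120-degree rotation about the cube diagonal) are the
  same cluster, so their probabilities are equal; and
* contact-class equivalence — the conditional probability of a neighbor
  state depends only on the components and the site classes of the two
  touching faces, not on the orientation of non-contacting faces.

Both are imposed structurally through :class:`PairTable` (one reduced
contact-class table shared by all three bonds); the explicit constraint
counts the reductions replace are still produced by enumeration in
:func:`count_model_bookkeeping`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .geometry import (
    CLUSTER_TOPOLOGY,
    Orientation,
    axis_cycle_rotation,
    compose,
    enumerate_orientations,
)
from .molecules import InteractionTable, MoleculeSpec

__all__ = [
    "MoleculeState",
    "ClusterState",
    "StateSpace",
    "Composition",
    "ClusterDistribution",
    "PairTable",
    "enumerate_cluster_states",
    "cluster_energy",
    "energies_4d",
    "cluster_probs_from_pairs",
    "system_entropy",
    "chain_rule_decomposition",
    "internal_energy",
    "helmholtz",
    "isotropy_classes",
    "IsotropyPartition",
    "count_model_bookkeeping",
    "contact_class_reduce",
]

#: probabilities below this are treated as exact zeros in entropy terms
PROB_FLOOR = 1e-15


class MoleculeState(NamedTuple):
    component_id: int
    orientation: Orientation


class ClusterState(NamedTuple):
    """Indices of the molecule states at cluster positions A, B, C, D."""

    a: int
    b: int
    c: int
    d: int


@dataclass(frozen=True)
class Composition:
    """Molar fractions of the two components, x_i = N_i / N."""

    x1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.x1 <= 1.0:
            raise ValueError(f"x1 must lie in [0, 1], got {self.x1}")

    @property
    def x2(self) -> float:
        return 1.0 - self.x1

    def fraction(self, component_index: int) -> float:
        return self.x1 if component_index == 0 else self.x2


class StateSpace:
    """Enumeration of molecule states and their contact-face bookkeeping.

    Parameters
    ----------
    specs : sequence of MoleculeSpec
        One or two components.
    sphere : bool
        Collapse orientations to a single one ("sphere mode"), reducing the
        model to the orientation-free mixing case.  Intended for molecules
        with a uniform surface.

    States are ordered component-major, then by orientation id.
    """

    def __init__(self, specs: Sequence[MoleculeSpec], sphere: bool = False):
        specs = tuple(specs)
        if not 1 <= len(specs) <= 2:
            raise ValueError("one or two component specs are required")
        self.specs = specs
        self.sphere = bool(sphere)
        self.orientations = (
            enumerate_orientations()[:1] if sphere else enumerate_orientations()
        )
        self.n_orient = len(self.orientations)
        self.n_comp = len(specs)
        self.n_states = self.n_comp * self.n_orient

        # state -> component index / orientation id
        self.state_comp = np.repeat(np.arange(self.n_comp), self.n_orient)
        self.state_orient = np.tile(np.arange(self.n_orient), self.n_comp)

        # distinct contact site types (component index, face class), sorted
        types = sorted(
            {(ci, c) for ci, s in enumerate(specs) for c in s.face_classes}
        )
        self.site_types: tuple[tuple[int, int], ...] = tuple(types)
        self._type_id = {t: k for k, t in enumerate(types)}
        self.n_types = len(types)

        # central_type[k, s]: type of state s's face at lab +axis_k
        # neighbor_type[k, s]: type of state s's face at lab -axis_k
        nst = self.n_states
        self.central_type = np.empty((3, nst), dtype=np.int64)
        self.neighbor_type = np.empty((3, nst), dtype=np.int64)
        for s in range(nst):
            ci = int(self.state_comp[s])
            spec = specs[ci]
            o = self.orientations[int(self.state_orient[s])]
            for k, bond in enumerate(CLUSTER_TOPOLOGY):
                face_out = o.body_face_along(bond)
                face_in = o.body_face_along(-bond)
                self.central_type[k, s] = self._type_id[(ci, spec.face_class(face_out))]
                self.neighbor_type[k, s] = self._type_id[(ci, spec.face_class(face_in))]

        # states per type at a fixed lab direction; identical across axes
        # and across the central/neighbor roles (4 orientations place a
        # given face along a given direction)
        counts = np.stack(
            [np.bincount(self.central_type[k], minlength=self.n_types) for k in range(3)]
            + [np.bincount(self.neighbor_type[k], minlength=self.n_types) for k in range(3)]
        )
        if not (counts == counts[0]).all():
            raise AssertionError("contact-type multiplicities differ across axes")
        self.type_multiplicity = counts[0]

    def state(self, index: int) -> MoleculeState:
        return MoleculeState(
            self.specs[int(self.state_comp[index])].component_id,
            self.orientations[int(self.state_orient[index])],
        )

    def single_probabilities(self, comp: Composition) -> np.ndarray:
        """p_a = x_i / n_orient for every state of component i."""
        x = np.array([comp.fraction(ci) for ci in range(self.n_comp)])
        if self.n_comp == 1:
            x = np.array([1.0])
        return x[self.state_comp] / self.n_orient

    def type_single_probability(self, comp: Composition) -> np.ndarray:
        """p0 per state, by site type (all states of one component share it)."""
        out = np.empty(self.n_types)
        for k, (ci, _cls) in enumerate(self.site_types):
            xi = 1.0 if self.n_comp == 1 else comp.fraction(ci)
            out[k] = xi / self.n_orient
        return out

    def bond_energy_matrices(self, table: InteractionTable) -> np.ndarray:
        """(3, n, n) array E[k, a, b]: energy of the bond along axis k
        between central state a and its +k neighbor in state b."""
        eps = self.type_energy_matrix(table)
        E = np.empty((3, self.n_states, self.n_states))
        for k in range(3):
            E[k] = eps[np.ix_(self.central_type[k], self.neighbor_type[k])]
        return E

    def type_energy_matrix(self, table: InteractionTable) -> np.ndarray:
        """(n_types, n_types) eps by (central face type, neighbor face type)."""
        eps = np.empty((self.n_types, self.n_types))
        for i, (_, ci) in enumerate(self.site_types):
            for j, (_, cj) in enumerate(self.site_types):
                eps[i, j] = table.energy(ci, cj)
        return eps

    def rotated_state_map(self) -> np.ndarray:
        """State permutation induced by the 120-degree diagonal rotation.

        In sphere mode orientations are frozen and the map is the identity.
        """
        if self.sphere:
            return np.arange(self.n_states)
        rho = axis_cycle_rotation()
        omap = np.array([compose(rho, o).id for o in self.orientations])
        return self.state_comp * self.n_orient + omap[self.state_orient]

    def __repr__(self) -> str:
        names = "+".join(s.name or f"comp{s.component_id}" for s in self.specs)
        mode = "sphere" if self.sphere else "dice"
        return f"StateSpace({names}, {mode}, n_states={self.n_states})"


def enumerate_cluster_states(space: StateSpace) -> Iterator[ClusterState]:
    """All cluster states in fixed a-major order (n_states^4 of them)."""
    n = range(space.n_states)
    for a, b, c, d in itertools.product(n, n, n, n):
        yield ClusterState(a, b, c, d)


def cluster_energy(
    cluster: ClusterState, space: StateSpace, table: InteractionTable
) -> float:
    """Additive three-bond energy e_abcd of one cluster state."""
    eps = space.type_energy_matrix(table)
    e = 0.0
    for k, nb in enumerate((cluster.b, cluster.c, cluster.d)):
        e += eps[space.central_type[k, cluster.a], space.neighbor_type[k, nb]]
    return float(e)


def energies_4d(space: StateSpace, table: InteractionTable) -> np.ndarray:
    """Full (n, n, n, n) array of cluster energies e_abcd."""
    E = space.bond_energy_matrices(table)
    return (
        E[0][:, :, None, None] + E[1][:, None, :, None] + E[2][:, None, None, :]
    )


class ClusterDistribution:
    """Probability distribution over cluster states p_abcd (4-D array)."""

    def __init__(self, p: np.ndarray, space: StateSpace | None = None):
        p = np.asarray(p, dtype=float)
        if p.ndim != 4 or len(set(p.shape)) != 1:
            raise ValueError("expected an (n, n, n, n) array")
        if (p < 0).any():
            raise ValueError("negative cluster probabilities")
        self.p = p
        self.space = space

    @property
    def n_states(self) -> int:
        return self.p.shape[0]

    def total(self) -> float:
        return float(self.p.sum())

    def neighborhood_marginal(self) -> np.ndarray:
        """p_bcd = sum_a p_abcd (law of total probability)."""
        return self.p.sum(axis=0)

    def component_marginal_a(self) -> np.ndarray:
        """Probability mass at position A per component (should equal x_i)."""
        if self.space is None:
            raise ValueError("component marginal requires a StateSpace")
        mass = self.p.sum(axis=(1, 2, 3))
        return np.bincount(self.space.state_comp, weights=mass,
                           minlength=self.space.n_comp)

    def validate(self, comp: Composition | None = None, tol: float = 1e-10) -> None:
        if abs(self.total() - 1.0) > tol:
            raise ValueError(f"probabilities sum to {self.total()}, not 1")
        if comp is not None and self.space is not None:
            marg = self.component_marginal_a()
            want = [comp.fraction(ci) for ci in range(self.space.n_comp)]
            if self.space.n_comp == 1:
                want = [1.0]
            if np.abs(marg - np.array(want)).max() > tol:
                raise ValueError(
                    f"component marginals {marg} do not match composition {want}"
                )

    def to_frame(self, threshold: float = 0.0):
        """Tidy table of cluster probabilities above ``threshold``."""
        import pandas as pd

        a, b, c, d = np.nonzero(self.p > threshold)
        return pd.DataFrame(
            {"a": a, "b": b, "c": c, "d": d, "probability": self.p[a, b, c, d]}
        )


class PairTable:
    """Single-state probabilities p_a and conditional pair probabilities.

    The optimizer's reduced variables.  Internally the conditionals are the
    contact-class table ``v[s, t]``: the probability that one *specific*
    neighbor state presenting site type t sits next to a central molecule
    presenting site type s at the contact.  One table serves all three bond
    axes (isotropy); the state-level matrices per axis differ only through
    which body faces make the contact.
    """

    def __init__(self, space: StateSpace, comp: Composition, v: np.ndarray):
        v = np.asarray(v, dtype=float)
        if v.shape != (space.n_types, space.n_types):
            raise ValueError("v must be (n_types, n_types)")
        if (v < -1e-14).any():
            raise ValueError("negative conditional probabilities")
        self.space = space
        self.composition = comp
        self.v = np.clip(v, 0.0, None)
        rows = self.row_sums()
        active = self._active_rows()
        if np.abs(rows[active] - 1.0).max() > 1e-8:
            raise ValueError(f"conditional rows do not sum to 1: {rows}")

    def _active_rows(self) -> np.ndarray:
        p0 = self.space.type_single_probability(self.composition)
        return p0 > 0

    def row_sums(self) -> np.ndarray:
        """sum_b p_{b|a} per central site type."""
        return self.v @ self.space.type_multiplicity

    @property
    def single(self) -> np.ndarray:
        """p_a per state (x_i / n_orient)."""
        return self.space.single_probabilities(self.composition)

    def cond_matrix(self, axis: int = 0) -> np.ndarray:
        """(n, n) state-level conditional p_{b|a} for the bond along ``axis``."""
        return self.v[
            np.ix_(self.space.central_type[axis], self.space.neighbor_type[axis])
        ]

    @property
    def cond(self) -> np.ndarray:
        """State-level conditional matrix for the reference (+x) axis."""
        return self.cond_matrix(0)

    @classmethod
    def random_mixing(cls, space: StateSpace, comp: Composition) -> "PairTable":
        """Neighbor independent of the centre: p_{b|a} = p_b."""
        p0 = space.type_single_probability(comp)
        v = np.tile(p0, (space.n_types, 1))
        return cls(space, comp, v)

    @classmethod
    def from_cond(
        cls,
        space: StateSpace,
        comp: Composition,
        cond_x: np.ndarray,
        tol: float = 1e-10,
    ) -> "PairTable":
        """Build from a full state-level +x conditional matrix, enforcing
        contact-class consistency (forward reduction)."""
        v = contact_class_reduce(space, cond_x, tol=tol)
        return cls(space, comp, v)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, s in enumerate(self.space.site_types):
            for j, t in enumerate(self.space.site_types):
                rows.append(
                    {
                        "central_component": s[0] + 1,
                        "central_class": s[1],
                        "neighbor_component": t[0] + 1,
                        "neighbor_class": t[1],
                        "p_state": self.v[i, j],
                        "p_group": self.v[i, j] * self.space.type_multiplicity[j],
                    }
                )
        return pd.DataFrame(rows)


def contact_class_reduce(
    space: StateSpace, cond_x: np.ndarray, tol: float = 1e-10
) -> np.ndarray:
    """Group a state-level conditional matrix by contact classes.

    Raises if states sharing the same (component, contact-face class) on
    both sides carry different conditional probabilities.
    """
    cond_x = np.asarray(cond_x, dtype=float)
    n = space.n_states
    if cond_x.shape != (n, n):
        raise ValueError("conditional matrix has wrong shape")
    v = np.full((space.n_types, space.n_types), np.nan)
    for a in range(n):
        sa = space.central_type[0, a]
        for b in range(n):
            tb = space.neighbor_type[0, b]
            if np.isnan(v[sa, tb]):
                v[sa, tb] = cond_x[a, b]
            elif abs(v[sa, tb] - cond_x[a, b]) > tol:
                raise ValueError(
                    "conditional matrix is not contact-class consistent "
                    f"at group ({space.site_types[sa]}, {space.site_types[tb]})"
                )
    return np.nan_to_num(v, nan=0.0)


def cluster_probs_from_pairs(pairs: PairTable) -> ClusterDistribution:
    """p_abcd = p_a p_{b|a} p_{c|a} p_{d|a} as a full 4-D distribution."""
    space = pairs.space
    pa = pairs.single
    cx = pairs.cond_matrix(0)
    cy = pairs.cond_matrix(1)
    cz = pairs.cond_matrix(2)
    p = (
        pa[:, None, None, None]
        * cx[:, :, None, None]
        * cy[:, None, :, None]
        * cz[:, None, None, :]
    )
    return ClusterDistribution(p, space)


def _xlogy_sum(p: np.ndarray, q: np.ndarray) -> float:
    """sum p * ln q over entries with p above the probability floor."""
    mask = p > PROB_FLOOR
    return float(np.sum(p[mask] * np.log(q[mask])))


def system_entropy(dist: ClusterDistribution) -> float:
    """S/(N k_B): conditional entropy of the inserted molecule given its
    neighborhood, -sum p_abcd ln(p_abcd / p_bcd); 0 ln 0 = 0."""
    p = dist.p
    if (p < 0).any():
        raise ValueError("negative probabilities")
    pn = dist.neighborhood_marginal()
    mask = p > PROB_FLOOR
    ratio = p[mask] / np.broadcast_to(pn, p.shape)[mask]
    return float(-np.sum(p[mask] * np.log(ratio)))


def chain_rule_decomposition(
    dist: ClusterDistribution,
) -> tuple[float, float, float]:
    """(S_cluster, S_neighborhood, S_system), all per molecule per k_B.

    The chain rule of Shannon entropy gives
    S_cluster = S_neighborhood + S_system for any distribution.
    """
    p = dist.p
    pn = dist.neighborhood_marginal()
    s_cluster = -_xlogy_sum(p, p)
    s_nbhd = -_xlogy_sum(pn, pn)
    return s_cluster, s_nbhd, system_entropy(dist)


def internal_energy(dist: ClusterDistribution, energies: np.ndarray) -> float:
    """U/(N k_B T): probability-weighted mean cluster energy."""
    return float(np.sum(dist.p * energies))


def helmholtz(dist: ClusterDistribution, energies: np.ndarray) -> float:
    """A/(N k_B T) = U/(N k_B T) - S/(N k_B)."""
    return internal_energy(dist, energies) - system_entropy(dist)


@dataclass
class IsotropyPartition:
    """Partition of the cluster-state set into equal-probability view classes."""

    n_states_total: int
    n_classes: int
    n_size3: int
    n_fixed: int

    @property
    def n_conditions(self) -> int:
        """Independent equal-probability conditions the partition implies
        (class size minus one per class)."""
        return self.n_states_total - self.n_classes


def _cluster_rotation_map(space: StateSpace) -> np.ndarray:
    """Flat-index permutation T of the cyclic bond-axis rotation.

    T sends cluster (a, b, c, d) to (ra, rd, rb, rc) where r is the state
    map of the 120-degree diagonal rotation: the rotated +x neighbor is the
    old +z one, and so on.
    """
    n = space.n_states
    r = space.rotated_state_map().astype(np.int64)
    idx = np.arange(n**4, dtype=np.int64)
    d = idx % n
    c = (idx // n) % n
    b = (idx // n**2) % n
    a = idx // n**3
    return ((r[a] * n + r[d]) * n + r[b]) * n + r[c]


def isotropy_classes(space: StateSpace) -> IsotropyPartition:
    """Partition all cluster states by the three equivalent viewing angles.

    For dice mode the diagonal rotation acts freely on orientations, so
    every class has exactly size 3; sphere mode admits fixed clusters
    (b = c = d) of class size 1.
    """
    T = _cluster_rotation_map(space)
    idx = np.arange(T.size, dtype=np.int64)
    t2 = T[T]
    if not (T[t2] == idx).all():
        raise AssertionError("axis rotation is not of order 3 on clusters")
    rep = np.minimum(np.minimum(idx, T), t2)
    n_classes = int((rep == idx).sum())
    n_fixed = int((T == idx).sum())
    n_total = int(T.size)
    n_size3 = (n_total - n_fixed) // 3
    if n_fixed + 3 * n_size3 != n_total:
        raise AssertionError("orbit sizes other than 1 and 3 encountered")
    return IsotropyPartition(n_total, n_classes, n_size3, n_fixed)


def iter_isotropy_orbits(space: StateSpace) -> Iterator[tuple[int, ...]]:
    """Explicit orbits as tuples of flat cluster indices (small spaces only)."""
    T = _cluster_rotation_map(space)
    seen = np.zeros(T.size, dtype=bool)
    for i in range(T.size):
        if seen[i]:
            continue
        orbit = [i]
        j = int(T[i])
        while j != i:
            orbit.append(j)
            j = int(T[j])
        for k in orbit:
            seen[k] = True
        yield tuple(orbit)


def _general_two_component_space() -> StateSpace:
    """Two components whose 12 faces are 12 distinct interaction sites."""
    m1 = MoleculeSpec(1, (1, 2, 3, 4, 5, 6), "General1")
    m2 = MoleculeSpec(2, (7, 8, 9, 10, 11, 12), "General2")
    return StateSpace((m1, m2))


def count_model_bookkeeping() -> dict[str, int]:
    """The model's constraint/variable bookkeeping for the general
    two-component dice case, produced by explicit enumeration.

    Returns a dict with:

    * ``cluster_variables_with_target`` — cluster probabilities plus the one
      target property (the free energy),
    * ``isotropy_conditions`` — equal-probability conditions from the three
      equivalent cluster views,
    * ``total_conditions`` — isotropy conditions plus normalization, the two
      composition marginals, and the objective,
    * ``site_pairs`` — distinct unordered pairs (with repetition) of the 12
      interaction sites,
    * ``free_pair_variables`` — symmetric pair-contact variables left free
      after one normalization per site,
    * ``orientations`` — proper rotations of a die.
    """
    space = _general_two_component_space()
    n_clusters = sum(1 for _ in enumerate_cluster_states(space))
    part = isotropy_classes(space)
    if part.n_fixed != 0:
        raise AssertionError("dice-mode isotropy classes must all have size 3")
    iso = part.n_conditions

    sites = sorted({(ci, c) for ci, s in enumerate(space.specs)
                    for c in s.face_classes})
    pairs = sum(1 for _ in itertools.combinations_with_replacement(sites, 2))
    normalizations = sum(1 for _ in sites)

    n_orient = sum(1 for _ in enumerate_orientations())

    # normalization (1) + two composition marginals (2) + objective (1)
    total = iso + 3 + 1
    return {
        "cluster_variables_with_target": n_clusters + 1,
        "isotropy_conditions": iso,
        "total_conditions": total,
        "site_pairs": pairs,
        "free_pair_variables": pairs - normalizations,
        "orientations": n_orient,
    }
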