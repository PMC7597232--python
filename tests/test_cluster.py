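"""Cluster-state enumeration, probability algebra, entropy/energy, counts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dicelattice as dl
from dicelattice.cluster import (
    ClusterState,
    Composition,
    PairTable,
    StateSpace,
    chain_rule_decomposition,
    cluster_energy,
    cluster_probs_from_pairs,
    contact_class_reduce,
    enumerate_cluster_states,
    energies_4d,
    helmholtz,
    internal_energy,
    isotropy_classes,
    iter_isotropy_orbits,
    system_entropy,
)
from dicelattice.geometry import contact_faces
from dicelattice.molecules import (
    builtin_molecule,
    table1_pattern,
    table_from_interchange,
    uniform_molecule,
)

from conftest import random_distribution


class TestStateEnumeration:
    def test_two_component_dice_state_count(self, angled_inert_space):
        assert angled_inert_space.n_states == 48

    def test_sphere_mode_single_component_single_state(self):
        space = StateSpace((uniform_molecule(1, 1),), sphere=True)
        assert space.n_states == 1
        assert sum(1 for _ in enumerate_cluster_states(space)) == 1

    def test_sphere_mode_two_components_sixteen_clusters(self, sphere_space):
        states = list(enumerate_cluster_states(sphere_space))
        assert len(states) == 16
        assert len(set(states)) == 16

    def test_enumeration_order_is_a_major(self, sphere_space):
        states = list(enumerate_cluster_states(sphere_space))
        assert states[0] == ClusterState(0, 0, 0, 0)
        assert states[1] == ClusterState(0, 0, 0, 1)
        assert states[-1] == ClusterState(1, 1, 1, 1)


class TestClusterEnergy:
    def test_all_inert_cluster_is_zero(self):
        space = StateSpace((builtin_molecule("inert", 1),))
        e = cluster_energy(ClusterState(0, 5, 11, 17), space, table1_pattern())
        assert e == 0.0

    def test_three_unlike_contacts_sum(self, sphere_specs):
        # uniform class-1 central with three uniform class-2 neighbors:
        # three 1-2 contacts at -1200 each
        space = StateSpace(sphere_specs, sphere=True)
        e = cluster_energy(ClusterState(0, 1, 1, 1), space, table1_pattern())
        assert e == -3600.0

    def test_one_like_contact_two_inert(self):
        # stretched die with class-1 face at +x meets its neighbor's class-1
        # face when the neighbor is rotated half a turn about z
        space = StateSpace((builtin_molecule("stretched", 1),
                            builtin_molecule("inert", 2)))
        half_z = next(
            o for o in space.orientations
            if o.perm == (1, 0, 3, 2, 4, 5)
        )
        b = half_z.id  # component 1, rotated
        inert0 = space.n_orient  # component 2, identity
        e = cluster_energy(ClusterState(0, b, inert0, inert0), space,
                           table1_pattern())
        assert e == 1200.0

    def test_energies_4d_matches_per_state_function(self, angled_inert_space):
        table = table_from_interchange(-4.0)
        E = energies_4d(angled_inert_space, table)
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 48, size=4)
            cs = ClusterState(int(a), int(b), int(c), int(d))
            assert E[a, b, c, d] == pytest.approx(
                cluster_energy(cs, angled_inert_space, table))

    def test_energy_equivariant_under_view_rotation(self, sphere_specs):
        """Members of an isotropy class share the cluster energy."""
        space = StateSpace(sphere_specs, sphere=True)
        E = energies_4d(space, table_from_interchange(-4.0)).ravel()
        for orbit in iter_isotropy_orbits(space):
            assert len(set(np.round(E[list(orbit)], 12))) == 1

    def test_energy_equivariance_full_dice_space(self, angled_inert_space):
        from dicelattice.cluster import _cluster_rotation_map

        E = energies_4d(angled_inert_space, table_from_interchange(-4.0)).ravel()
        T = _cluster_rotation_map(angled_inert_space)
        assert np.abs(E - E[T]).max() < 1e-12


class TestPairTableAndFactorization:
    def test_random_mixing_pairs_reproduce_product_form(self, angled_inert_space):
        comp = Composition(0.3)
        pairs = PairTable.random_mixing(angled_inert_space, comp)
        dist = cluster_probs_from_pairs(pairs)
        pa = pairs.single
        expected = (
            pa[:, None, None, None] * pa[None, :, None, None]
            * pa[None, None, :, None] * pa[None, None, None, :]
        )
        assert np.abs(dist.p - expected).max() < 1e-15

    def test_uniform_conditionals_equimolar(self, angled_inert_space):
        pairs = PairTable.random_mixing(angled_inert_space, Composition(0.5))
        dist = cluster_probs_from_pairs(pairs)
        # p_a = x1/24 = 1/48, so every cluster has probability (1/48)^4
        assert dist.p.flat[0] == pytest.approx((1 / 48) ** 4)

    def test_constructed_distribution_satisfies_constraints(
        self, angled_inert_space
    ):
        rng = np.random.default_rng(42)
        comp = Composition(0.37)
        v = _random_valid_v(angled_inert_space, comp, rng)
        pairs = PairTable(angled_inert_space, comp, v)
        dist = cluster_probs_from_pairs(pairs)
        assert dist.total() == pytest.approx(1.0, abs=1e-12)
        marg = dist.component_marginal_a()
        assert marg[0] == pytest.approx(0.37, abs=1e-12)
        assert marg[1] == pytest.approx(0.63, abs=1e-12)

    def test_invalid_rows_raise(self, angled_inert_space):
        v = np.full((4, 4), 0.5)
        with pytest.raises(ValueError, match="rows"):
            PairTable(angled_inert_space, Composition(0.5), v)

    def test_contact_class_roundtrip(self, angled_inert_space):
        rng = np.random.default_rng(3)
        comp = Composition(0.6)
        v = _random_valid_v(angled_inert_space, comp, rng)
        pairs = PairTable(angled_inert_space, comp, v)
        cond = pairs.cond
        v_back = contact_class_reduce(angled_inert_space, cond)
        assert np.abs(v_back - v).max() < 1e-12

    def test_contact_class_reduce_rejects_inconsistent(self, angled_inert_space):
        comp = Composition(0.5)
        pairs = PairTable.random_mixing(angled_inert_space, comp)
        cond = pairs.cond.copy()
        cond[0, 0] += 0.1
        with pytest.raises(ValueError, match="consistent"):
            contact_class_reduce(angled_inert_space, cond)

    def test_inert_component_rows_uniform_over_orientations(self, angled, inert):
        """All 24 orientations of an inert neighbor are equally likely."""
        space = StateSpace((angled, inert))
        pairs = PairTable.random_mixing(space, Composition(0.5))
        cond = pairs.cond
        inert_cols = np.flatnonzero(space.state_comp == 1)
        row = cond[0, inert_cols]
        assert np.ptp(row) == 0.0

    def test_stretched_contact_orientation_counts(self, stretched):
        """4 orientations present the class-1 face, 4 the class-2 face,
        16 a class-0 face at a fixed contact direction."""
        space = StateSpace((stretched,))
        by_type = np.bincount(space.neighbor_type[0], minlength=space.n_types)
        counts = {space.site_types[t]: int(n) for t, n in enumerate(by_type)}
        assert counts[(0, 1)] == 4 and counts[(0, 2)] == 4 and counts[(0, 0)] == 16


class TestEntropy:
    def test_independent_uniform_entropy_ln48(self, angled_inert_space):
        pairs = PairTable.random_mixing(angled_inert_space, Composition(0.5))
        dist = cluster_probs_from_pairs(pairs)
        assert system_entropy(dist) == pytest.approx(np.log(48), abs=1e-10)

    def test_pure_component_sphere_mode_zero(self):
        space = StateSpace((uniform_molecule(1, 1),), sphere=True)
        dist = cluster_probs_from_pairs(
            PairTable.random_mixing(space, Composition(1.0)))
        assert system_entropy(dist) == 0.0

    @pytest.mark.parametrize("x1", [0.1, 0.5, 0.8])
    def test_sphere_random_mixing_is_binary_entropy(self, sphere_space, x1):
        dist = cluster_probs_from_pairs(
            PairTable.random_mixing(sphere_space, Composition(x1)))
        expected = -(x1 * np.log(x1) + (1 - x1) * np.log(1 - x1))
        assert system_entropy(dist) == pytest.approx(expected, abs=1e-12)

    def test_negative_probabilities_rejected(self):
        p = np.full((2, 2, 2, 2), 1 / 16.0)
        p[0, 0, 0, 0] = -0.01
        with pytest.raises(ValueError):
            dl.ClusterDistribution(p)

    def test_deterministic_distribution_all_entropies_zero(self):
        p = np.zeros((3, 3, 3, 3))
        p[1, 2, 0, 1] = 1.0
        sc, sn, ss = chain_rule_decomposition(dl.ClusterDistribution(p))
        assert (sc, sn, ss) == (0.0, 0.0, 0.0)

    def test_independent_uniform_chain_rule_values(self, angled_inert_space):
        pairs = PairTable.random_mixing(angled_inert_space, Composition(0.5))
        dist = cluster_probs_from_pairs(pairs)
        sc, sn, ss = chain_rule_decomposition(dist)
        assert sc == pytest.approx(4 * np.log(48), abs=1e-9)
        assert sn == pytest.approx(3 * np.log(48), abs=1e-9)
        assert ss == pytest.approx(np.log(48), abs=1e-9)

    @given(st.integers(0, 10_000), st.integers(2, 4))
    def test_chain_rule_identity_fuzzed(self, seed, n):
        """S_cluster = S_neighborhood + S_system for any distribution."""
        dist = random_distribution(n, np.random.default_rng(seed))
        sc, sn, ss = chain_rule_decomposition(dist)
        assert sc == pytest.approx(sn + ss, abs=1e-10)

    def test_entropy_nonnegative_and_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            dist = random_distribution(3, rng)
            s = system_entropy(dist)
            assert -1e-12 <= s <= np.log(81) + 1e-12


class TestEnergyFunctionals:
    def test_weighted_mean_toy_distribution(self):
        p = np.zeros((2, 2, 2, 2))
        p[0, 0, 0, 0] = 0.25
        p[1, 1, 1, 1] = 0.75
        e = np.zeros_like(p)
        e[0, 0, 0, 0] = -4.0
        assert internal_energy(dl.ClusterDistribution(p), e) == pytest.approx(-1.0)

    def test_zero_table_energy_and_helmholtz_identity(self, angled_inert_space):
        table = table_from_interchange(0.0)
        pairs = PairTable.random_mixing(angled_inert_space, Composition(0.5))
        dist = cluster_probs_from_pairs(pairs)
        E = energies_4d(angled_inert_space, table)
        assert internal_energy(dist, E) == 0.0
        assert helmholtz(dist, E) == pytest.approx(
            -(np.log(24) + np.log(2)), abs=1e-10)

    @given(st.integers(0, 1000))
    def test_helmholtz_is_u_minus_s(self, seed):
        rng = np.random.default_rng(seed)
        dist = random_distribution(3, rng)
        e = rng.normal(size=(3, 3, 3, 3))
        assert helmholtz(dist, e) == pytest.approx(
            internal_energy(dist, e) - system_entropy(dist), abs=1e-12)


class TestIsotropy:
    def test_sphere_space_partition(self, sphere_space):
        part = isotropy_classes(sphere_space)
        assert part.n_states_total == 16
        # fixed clusters have b = c = d: 2 choices of a x 2 of b
        assert part.n_fixed == 4
        assert part.n_size3 == 4
        assert part.n_classes == 8
        orbits = list(iter_isotropy_orbits(sphere_space))
        assert sorted(len(o) for o in orbits) == [1, 1, 1, 1, 3, 3, 3, 3]
        assert sum(len(o) for o in orbits) == 16

    def test_dice_space_classes_all_size_three(self, angled, inert):
        space = StateSpace((angled, inert))
        part = isotropy_classes(space)
        assert part.n_fixed == 0
        assert part.n_size3 * 3 == 48**4
        assert part.n_conditions == 2 * part.n_size3


class TestBookkeepingCounts:
    def test_site_pair_combinatorics(self):
        counts = dl.count_model_bookkeeping()
        assert counts["site_pairs"] == 78
        assert counts["free_pair_variables"] == 66
        assert counts["orientations"] == 24

    def test_composition_validation(self):
        with pytest.raises(ValueError):
            Composition(1.2)
        c = Composition(0.25)
        assert c.x2 == 0.75


def _random_valid_v(space, comp, rng):
    """A random contact-class-consistent conditional table."""
    p0 = space.type_single_probability(comp)
    n = space.n_types
    raw = rng.uniform(0.2, 1.0, size=(n, n))
    active = p0 > 0
    v = np.zeros((n, n))
    mult = space.type_multiplicity
    for s in range(n):
        if not active[s]:
            continue
        w = raw[s] * active
        v[s] = w / (w @ mult)
    return v
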