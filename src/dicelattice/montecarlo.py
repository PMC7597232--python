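"""Metropolis Monte Carlo of orientable dice on a periodic simple cubic lattice.

The benchmark for the cluster model: every site of an L x L x L periodic
lattice holds one molecule (component + orientation); bond energies are the
same contact-face lookups the cluster model uses.  Moves are single-site
re-orientations and composition-conserving two-site content swaps, accepted
with probability min(1, exp(-beta_hat * dE)) where beta_hat scales the
dimensionless interaction table (the role of an inverse temperature).

Sampled mean energies over a beta_hat schedule starting at 0 are integrated
to the Helmholtz free energy with the Gibbs-Helmholtz identity
d(A/NkT)/dbeta_hat = U0, where U0 is the mean *unscaled* bond energy per
molecule, from the exactly known infinite-temperature reference
A0/(NkT) = sum_i x_i ln x_i - ln(n_orientations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .cluster import Composition, StateSpace
from .molecules import InteractionTable, MoleculeSpec

__all__ = [
    "LatticeState",
    "McRun",
    "total_energy",
    "metropolis_step",
    "run_simulation",
    "sample_configurations",
    "gibbs_helmholtz_integrate",
]


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _energy_around(state, neigh, Eb, i):
    e = 0.0
    for k in range(3):
        e += Eb[k, state[i], state[neigh[i, 2 * k]]]
        e += Eb[k, state[neigh[i, 2 * k + 1]], state[i]]
    return e


@njit(cache=True)
def _total_energy_kernel(state, neigh, Eb):
    e = 0.0
    for i in range(state.shape[0]):
        for k in range(3):
            e += Eb[k, state[i], state[neigh[i, 2 * k]]]
    return e


@njit(cache=True)
def _swap_delta(state, neigh, Eb, i, j):
    """Energy change of swapping the contents of sites i and j, counting
    every affected bond exactly once (bonds between i and j would otherwise
    be double counted, including the L=2 wrap-around case)."""
    e_old = _energy_around(state, neigh, Eb, i) + _energy_around(state, neigh, Eb, j)
    shared_old = 0.0
    for k in range(3):
        if neigh[i, 2 * k] == j:
            shared_old += Eb[k, state[i], state[j]]
        if neigh[i, 2 * k + 1] == j:
            shared_old += Eb[k, state[j], state[i]]
    si, sj = state[i], state[j]
    state[i], state[j] = sj, si
    e_new = _energy_around(state, neigh, Eb, i) + _energy_around(state, neigh, Eb, j)
    shared_new = 0.0
    for k in range(3):
        if neigh[i, 2 * k] == j:
            shared_new += Eb[k, state[i], state[j]]
        if neigh[i, 2 * k + 1] == j:
            shared_new += Eb[k, state[j], state[i]]
    state[i], state[j] = si, sj
    return (e_new - shared_new) - (e_old - shared_old)


@njit(cache=True)
def _mc_kernel(
    state,
    neigh,
    Eb,
    beta,
    n_sweeps,
    steps_per_sweep,
    p_rot,
    n_orient,
    seed,
    record_config,
):
    """Run n_sweeps sweeps; returns (per-sweep total energies, accepted,
    attempted, per-sweep component bitmasks if record_config)."""
    np.random.seed(seed)
    n_sites = state.shape[0]
    energy = _total_energy_kernel(state, neigh, Eb)
    energies = np.empty(n_sweeps)
    configs = np.zeros(n_sweeps if record_config else 1, dtype=np.int64)
    accepted = 0
    attempted = 0
    for sweep in range(n_sweeps):
        for _ in range(steps_per_sweep):
            attempted += 1
            if np.random.random() < p_rot:
                i = np.random.randint(n_sites)
                old = state[i]
                comp = old // n_orient
                new = comp * n_orient + np.random.randint(n_orient)
                if new == old:
                    accepted += 1
                    continue
                e_old = _energy_around(state, neigh, Eb, i)
                state[i] = new
                e_new = _energy_around(state, neigh, Eb, i)
                d_e = e_new - e_old
                if d_e <= 0.0 or np.random.random() < np.exp(-beta * d_e):
                    accepted += 1
                    energy += d_e
                else:
                    state[i] = old
            else:
                i = np.random.randint(n_sites)
                j = np.random.randint(n_sites)
                if i == j or state[i] == state[j]:
                    accepted += 1
                    continue
                d_e = _swap_delta(state, neigh, Eb, i, j)
                if d_e <= 0.0 or np.random.random() < np.exp(-beta * d_e):
                    accepted += 1
                    si = state[i]
                    state[i] = state[j]
                    state[j] = si
                    energy += d_e
        energies[sweep] = energy
        if record_config:
            mask = np.int64(0)
            for i in range(n_sites):
                if state[i] // n_orient == 1:
                    mask |= np.int64(1) << np.int64(i)
            configs[sweep] = mask
    return energies, accepted, attempted, configs


# --------------------------------------------------------------------------
# lattice container
# --------------------------------------------------------------------------

def _neighbor_table(L: int) -> np.ndarray:
    """(L^3, 6) site indices of the +x,-x,+y,-y,+z,-z periodic neighbors."""
    idx = np.arange(L**3).reshape(L, L, L)
    neigh = np.empty((L**3, 6), dtype=np.int64)
    for k, axis in enumerate((0, 1, 2)):
        neigh[:, 2 * k] = np.roll(idx, -1, axis=axis).ravel()
        neigh[:, 2 * k + 1] = np.roll(idx, 1, axis=axis).ravel()
    return neigh


class LatticeState:
    """An L x L x L periodic arrangement of molecule states.

    Component counts are fixed at round(x1 * L^3) and conserved by all
    moves; orientations start uniformly random (dice mode).
    """

    def __init__(
        self,
        space: StateSpace,
        L: int,
        comp: Composition,
        rng: np.random.Generator,
    ):
        if L < 2:
            raise ValueError("edge length must be at least 2")
        self.space = space
        self.L = int(L)
        self.composition = comp
        n_sites = L**3
        n1 = int(round(comp.x1 * n_sites)) if space.n_comp == 2 else n_sites
        comps = np.zeros(n_sites, dtype=np.int64)
        comps[n1:] = 1 if space.n_comp == 2 else 0
        rng.shuffle(comps)
        orients = rng.integers(0, space.n_orient, size=n_sites)
        self.state = (comps * space.n_orient + orients).astype(np.int64)
        self.neigh = _neighbor_table(L)

    @property
    def n_sites(self) -> int:
        return self.L**3

    def component_counts(self) -> np.ndarray:
        return np.bincount(self.state // self.space.n_orient,
                           minlength=self.space.n_comp)

    def snapshot(self) -> dict:
        """JSON-serializable snapshot (components and orientations per site)."""
        return {
            "L": self.L,
            "x1": self.composition.x1,
            "components": (self.state // self.space.n_orient).tolist(),
            "orientations": (self.state % self.space.n_orient).tolist(),
        }

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.snapshot()) + "\n")


def total_energy(
    lattice: LatticeState, table: InteractionTable
) -> float:
    """Total bond energy per molecule (3 L^3 bonds, each counted once)."""
    Eb = lattice.space.bond_energy_matrices(table)
    e = _total_energy_kernel(lattice.state, lattice.neigh, Eb)
    return float(e) / lattice.n_sites


def metropolis_step(
    lattice: LatticeState,
    rng: np.random.Generator,
    beta: float,
    table: InteractionTable,
    rotation_fraction: float = 0.5,
) -> bool:
    """One Metropolis move (rotation or swap); returns the accept flag.

    A convenience single-step wrapper over the same kernel the production
    runs use; dE is computed from the affected bonds only.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    Eb = lattice.space.bond_energy_matrices(table)
    seed = int(rng.integers(0, 2**31 - 1))
    _, accepted, _, _ = _mc_kernel(
        lattice.state, lattice.neigh, Eb, float(beta), 1, 1,
        float(rotation_fraction), lattice.space.n_orient, seed, False,
    )
    return bool(accepted)


@dataclass(frozen=True)
class McRun:
    """Controls for a Monte-Carlo run over a beta_hat schedule."""

    seed: int = 0
    L: int = 10
    equilibration_sweeps: int = 2000
    sampling_sweeps: int = 10000
    rotation_fraction: float = 0.5
    betas: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 12))
    n_blocks: int = 10

    def __post_init__(self) -> None:
        if self.n_blocks < 10:
            raise ValueError("at least 10 blocks are required for the SE")
        if len(self.betas) and self.betas[0] != 0.0:
            raise ValueError("the beta_hat schedule must start at 0")


def run_simulation(
    specs: Sequence[MoleculeSpec],
    table: InteractionTable,
    comp: Composition,
    run: McRun,
    sphere: bool = False,
) -> pd.DataFrame:
    """Sampled mean energy per molecule over the beta_hat schedule.

    The lattice is annealed along the schedule (each point starts from the
    previous equilibrated state).  U is the mean *unscaled* bond energy per
    molecule; the standard error comes from >= 10 block averages.
    Deterministic given ``run.seed``.
    """
    space = StateSpace(specs, sphere=sphere)
    Eb = space.bond_energy_matrices(table)
    rng = np.random.default_rng(run.seed)
    lattice = LatticeState(space, run.L, comp, rng)
    steps = lattice.n_sites
    p_rot = 0.0 if space.n_orient == 1 else run.rotation_fraction
    rows = []
    for beta in run.betas:
        seed_eq = int(rng.integers(0, 2**31 - 1))
        seed_sm = int(rng.integers(0, 2**31 - 1))
        _mc_kernel(lattice.state, lattice.neigh, Eb, float(beta),
                   run.equilibration_sweeps, steps, p_rot,
                   space.n_orient, seed_eq, False)
        energies, acc, att, _ = _mc_kernel(
            lattice.state, lattice.neigh, Eb, float(beta),
            run.sampling_sweeps, steps, p_rot,
            space.n_orient, seed_sm, False,
        )
        u = energies / lattice.n_sites
        blocks = np.array_split(u, run.n_blocks)
        means = np.array([b.mean() for b in blocks])
        rows.append(
            {
                "beta": float(beta),
                "U": float(u.mean()),
                "U_se": float(means.std(ddof=1) / np.sqrt(len(means))),
                "acceptance": acc / att if att else float("nan"),
                "n_sweeps": run.sampling_sweeps,
            }
        )
    return pd.DataFrame(rows)


def sample_configurations(
    specs: Sequence[MoleculeSpec],
    table: InteractionTable,
    comp: Composition,
    L: int,
    beta: float,
    n_sweeps: int,
    seed: int,
    equilibration_sweeps: int = 1000,
    sphere: bool = True,
) -> np.ndarray:
    """Per-sweep component bitmasks of a small lattice (<= 63 sites).

    Used to compare the empirical stationary distribution over explicit
    configurations against Boltzmann weights (detailed-balance check).
    """
    space = StateSpace(specs, sphere=sphere)
    if L**3 > 63:
        raise ValueError("configuration recording is limited to <= 63 sites")
    Eb = space.bond_energy_matrices(table)
    rng = np.random.default_rng(seed)
    lattice = LatticeState(space, L, comp, rng)
    steps = lattice.n_sites
    p_rot = 0.0 if space.n_orient == 1 else 0.5
    _mc_kernel(lattice.state, lattice.neigh, Eb, float(beta),
               equilibration_sweeps, steps, p_rot, space.n_orient,
               int(rng.integers(0, 2**31 - 1)), False)
    _, _, _, configs = _mc_kernel(
        lattice.state, lattice.neigh, Eb, float(beta), n_sweeps, steps,
        p_rot, space.n_orient, int(rng.integers(0, 2**31 - 1)), True,
    )
    return configs


def gibbs_helmholtz_integrate(
    betas: Sequence[float],
    U: Sequence[float],
    comp: Composition,
    n_orient: int = 24,
    U_se: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Integrate sampled energies to the dimensionless free energy.

    A(beta)/(N kB T) = A0 + ∫_0^beta U0 dbeta' by the trapezoidal rule,
    with the infinite-temperature reference
    A0 = sum_i x_i ln x_i - ln(n_orient).  Sampling errors, if given, are
    propagated through the quadrature.
    """
    betas = np.asarray(betas, dtype=float)
    U = np.asarray(U, dtype=float)
    if betas[0] != 0.0:
        raise ValueError("the beta grid must start at 0")
    if np.any(np.diff(betas) <= 0):
        raise ValueError("the beta grid must be strictly increasing")
    x1 = comp.x1
    a0 = -np.log(n_orient)
    for x in (x1, 1.0 - x1):
        if x > 0:
            a0 += x * np.log(x)
    dbeta = np.diff(betas)
    increments = dbeta * (U[:-1] + U[1:]) / 2.0
    A = a0 + np.concatenate(([0.0], np.cumsum(increments)))
    out = pd.DataFrame({"beta": betas, "A": A})
    if U_se is not None:
        se = np.asarray(U_se, dtype=float)
        var_inc = (dbeta / 2.0) ** 2 * (se[:-1] ** 2 + se[1:] ** 2)
        out["A_se"] = np.sqrt(np.concatenate(([0.0], np.cumsum(var_inc))))
    return out
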