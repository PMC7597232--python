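"""Equilibrium of the cluster model: constrained Helmholtz minimization.

The free variables of the minimization are the symmetric contact-pair
probabilities eta[s, t] — the joint probability that a specific central
state presenting site type s and a specific neighbor state presenting site
type t touch across a bond.  Row sums are pinned to the single-state
probabilities (sum_t n_t eta[s, t] = p0_s, with p0_s = x_i / 24), which is
the per-site normalization that leaves 66 free variables in the general
two-component case.  Positivity and the row constraints are made structural
by writing eta as a symmetric diagonal (Sinkhorn) scaling of positive
weights exp(w), leaving an unconstrained smooth minimization over w; the
random-mixing solution is exactly w = 0.

The objective A/(N k_B T) = U/(N k_B T) - S/(N k_B) is evaluated on the
contact-class level: cluster probabilities depend on the neighbors only
through their contact types, so the 48^4 sums collapse to sums over
(central group) x (three neighbor types) — a few thousand terms.  The full
48^4 path in :mod:`dicelattice.cluster` serves as the brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .cluster import (
    ClusterDistribution,
    Composition,
    PairTable,
    StateSpace,
    cluster_probs_from_pairs,
    energies_4d,
)
from .molecules import InteractionTable, MoleculeSpec, builtin_molecule, table_from_interchange

__all__ = [
    "SolveSpec",
    "ThermoPoint",
    "EquilibriumResult",
    "DiceMixtureModel",
    "solve_equilibrium",
    "random_mixing_point",
    "solve_curve",
    "gibbs_helmholtz_check",
]

_XTINY = 1e-12  # compositions closer than this to 0/1 are treated as pure
_PFLOOR = 1e-300


@dataclass(frozen=True)
class SolveSpec:
    """Inputs and solver controls for one equilibrium point."""

    specs: tuple[MoleculeSpec, ...]
    table: InteractionTable
    composition: Composition
    sphere: bool = False
    tol: float = 1e-10
    max_iter: int = 1000
    restarts: int = 5
    seed: int = 0
    mixing_reference: bool = True

    def with_x1(self, x1: float) -> "SolveSpec":
        return replace(self, composition=Composition(x1))

    def with_table(self, table: InteractionTable) -> "SolveSpec":
        return replace(self, table=table)


@dataclass
class ThermoPoint:
    """Equilibrium state functions at one composition/coupling, all
    dimensionless (entropy per N k_B, energies per N k_B T)."""

    S_per_NkB: float
    U_per_NkBT: float
    A_per_NkBT: float
    A_mix_per_NkBT: float
    converged: bool
    n_iterations: int = 0
    grad_norm: float = float("nan")
    restart_index: int = 0

    def __post_init__(self) -> None:
        if abs(self.A_per_NkBT - (self.U_per_NkBT - self.S_per_NkB)) > 1e-9:
            raise ValueError("A != U - S beyond tolerance")


class _ReducedSystem:
    """Contact-class-level evaluation of S, U and A for one SolveSpec."""

    def __init__(self, space: StateSpace, comp: Composition, table: InteractionTable):
        self.space = space
        self.comp = comp
        p0_all = space.type_single_probability(comp)
        self.active = np.flatnonzero(p0_all > _XTINY)
        self.p0 = p0_all[self.active]  # single-state prob per active type
        self.mult = space.type_multiplicity[self.active].astype(float)
        self.n = len(self.active)
        # map full type id -> active index
        self._a_of = {int(t): k for k, t in enumerate(self.active)}

        eps_full = space.type_energy_matrix(table)
        self.eps = eps_full[np.ix_(self.active, self.active)]

        # group central states of present components by their three
        # contact types at +x, +y, +z
        if space.n_comp > 1:
            xs = np.array([comp.fraction(ci) for ci in range(space.n_comp)])
            present_states = np.flatnonzero(xs[space.state_comp] > _XTINY)
        else:
            present_states = np.arange(space.n_states)
        groups: dict[tuple[int, int, int], int] = {}
        g_count: list[int] = []
        g_types: list[tuple[int, int, int]] = []
        g_p0: list[float] = []
        p_single = space.single_probabilities(comp)
        for s in present_states:
            key = (
                self._a_of[int(space.central_type[0, s])],
                self._a_of[int(space.central_type[1, s])],
                self._a_of[int(space.central_type[2, s])],
            )
            if key not in groups:
                groups[key] = len(g_types)
                g_types.append(key)
                g_count.append(0)
                g_p0.append(float(p_single[s]))
            g = groups[key]
            g_count[g] += 1
            # all states of one component share p_a; nothing to accumulate
        self.g_types = np.array(g_types, dtype=np.int64)  # (G, 3)
        self.g_mult = np.array(g_count, dtype=float)
        self.g_p0 = np.array(g_p0)
        G = len(g_types)
        gx, gy, gz = self.g_types.T
        # cluster energy per (group, t1, t2, t3)
        self.E4 = (
            self.eps[gx][:, :, None, None]
            + self.eps[gy][:, None, :, None]
            + self.eps[gz][:, None, None, :]
        )
        # state multiplicity weight per cell
        self.W4 = (
            self.g_mult[:, None, None, None]
            * self.mult[None, :, None, None]
            * self.mult[None, None, :, None]
            * self.mult[None, None, None, :]
        )

    # --- symmetric Sinkhorn scaling -------------------------------------
    def eta_from_weights(self, K: np.ndarray, tol: float = 1e-14,
                         max_iter: int = 5000) -> tuple[np.ndarray, bool]:
        """Scale symmetric positive K to eta = diag(lam) K diag(lam) with
        row sums sum_t n_t eta[s,t] = p0_s."""
        lam = np.sqrt(self.p0 / np.maximum(K @ self.mult, _PFLOOR))
        ok = False
        for _ in range(max_iter):
            rows = lam * (K @ (self.mult * lam))
            err = np.abs(rows / self.p0 - 1.0).max()
            if err < tol:
                ok = True
                break
            lam = lam * np.sqrt(self.p0 / np.maximum(rows, _PFLOOR))
        eta = (lam[:, None] * lam[None, :]) * K
        return eta, ok

    def v_from_w(self, w_tri: np.ndarray) -> tuple[np.ndarray, bool]:
        """Conditional table v[s,t] = eta[s,t]/p0_s from free log-weights."""
        K = self._K_from_tri(w_tri)
        eta, ok = self.eta_from_weights(K)
        v = eta / self.p0[:, None]
        return v, ok

    def _K_from_tri(self, w_tri: np.ndarray) -> np.ndarray:
        # eta is invariant under scaling K, so shift w for a safe exp range
        w_tri = np.asarray(w_tri, dtype=float)
        w_tri = np.clip(w_tri - w_tri.max(), -500.0, 0.0)
        iu = np.triu_indices(self.n)
        K = np.zeros((self.n, self.n))
        K[iu] = np.exp(w_tri)
        K = K + K.T - np.diag(np.diag(K))
        return K

    @property
    def n_free(self) -> int:
        return self.n * (self.n + 1) // 2

    # --- thermodynamic functions ----------------------------------------
    def evaluate(self, v: np.ndarray) -> tuple[float, float, float]:
        """(A, U, S) per molecule for a conditional table v (active types)."""
        gx, gy, gz = self.g_types.T
        Vx = v[gx]  # (G, n)
        Vy = v[gy]
        Vz = v[gz]
        P4 = (
            self.g_p0[:, None, None, None]
            * Vx[:, :, None, None]
            * Vy[:, None, :, None]
            * Vz[:, None, None, :]
        )
        Pn = np.einsum("g,gijk->ijk", self.g_mult, P4)
        Pf = np.maximum(P4, _PFLOOR)
        lnratio = np.log(Pf) - np.log(np.maximum(Pn, _PFLOOR))[None]
        mask = P4 > 1e-15
        S = -float(np.sum((self.W4 * P4 * lnratio)[mask]))
        U = float(np.sum(self.W4 * P4 * self.E4))
        return U - S, U, S

    def objective(self, w_tri: np.ndarray) -> float:
        v, _ = self.v_from_w(w_tri)
        a = self.evaluate(v)[0]
        return a if np.isfinite(a) else 1e6

    def expand_v(self, v_active: np.ndarray) -> np.ndarray:
        """Embed an active-type conditional table into the full type set."""
        full = np.zeros((self.space.n_types, self.space.n_types))
        full[np.ix_(self.active, self.active)] = v_active
        return full


class EquilibriumResult:
    """Result of one equilibrium solve: state functions, pair table, and
    access to the underlying full cluster distribution."""

    def __init__(
        self,
        spec: SolveSpec,
        space: StateSpace,
        thermo: ThermoPoint,
        pairs: PairTable,
        w: np.ndarray,
    ):
        self.spec = spec
        self.space = space
        self.thermo = thermo
        self.pairs = pairs
        self.w = w
        self._dist: ClusterDistribution | None = None

    def distribution(self) -> ClusterDistribution:
        """Full cluster distribution p_abcd (materialized lazily)."""
        if self._dist is None:
            self._dist = cluster_probs_from_pairs(self.pairs)
        return self._dist

    @property
    def converged(self) -> bool:
        return self.thermo.converged

    def summary(self) -> str:
        t = self.thermo
        names = " + ".join(s.name or f"component {s.component_id}"
                           for s in self.spec.specs)
        lines = [
            "Cluster-model equilibrium",
            "=" * 48,
            f"mixture:          {names}",
            f"mode:             {'sphere' if self.spec.sphere else 'dice'}",
            f"x1:               {self.spec.composition.x1:.6g}",
            f"S/(N kB):         {t.S_per_NkB: .9f}",
            f"U/(N kB T):       {t.U_per_NkBT: .9f}",
            f"A/(N kB T):       {t.A_per_NkBT: .9f}",
            f"A_mix/(N kB T):   {t.A_mix_per_NkBT: .9f}",
            f"converged:        {t.converged}"
            f"  (iterations={t.n_iterations},"
            f" |grad|={t.grad_norm:.2e}, restart={t.restart_index})",
        ]
        return "\n".join(lines)


def random_mixing_point(spec: SolveSpec) -> ThermoPoint:
    """Closed-form random-mixing state functions (no optimization).

    Neighbor states independent of the centre: S/(N k_B) = ln(n_orient)
    - sum_i x_i ln x_i, U is three bonds times the mean contact energy of
    independent uniformly oriented states.
    """
    space = StateSpace(spec.specs, sphere=spec.sphere)
    comp = spec.composition
    sys = _ReducedSystem(space, comp, spec.table)
    v_rm = np.tile(sys.p0, (sys.n, 1))
    A, U, S = sys.evaluate(v_rm)
    a_mix = A - _pure_reference(spec, random_mixing=True) if spec.mixing_reference else float("nan")
    return ThermoPoint(S, U, A, a_mix, converged=True)


def _pure_reference(spec: SolveSpec, random_mixing: bool = False) -> float:
    """x-weighted pure-component free energies, the mixing reference."""
    comp = spec.composition
    ref = 0.0
    for ci, x in ((0, comp.x1), (1, comp.x2)):
        if ci >= len(spec.specs) or x <= _XTINY:
            continue
        pure = SolveSpec(
            specs=(spec.specs[ci] if len(spec.specs) > 1 else spec.specs[0],),
            table=spec.table,
            composition=Composition(1.0),
            sphere=spec.sphere,
            tol=spec.tol,
            max_iter=spec.max_iter,
            restarts=spec.restarts,
            seed=spec.seed,
            mixing_reference=False,
        )
        if random_mixing:
            ref += x * random_mixing_point(pure).A_per_NkBT
        else:
            ref += x * solve_equilibrium(pure).thermo.A_per_NkBT
    return ref


def solve_equilibrium(
    spec: SolveSpec, warm_start: np.ndarray | None = None
) -> EquilibriumResult:
    """Minimize the dimensionless Helmholtz free energy over the symmetric
    pair-contact weights.

    Runs ``spec.restarts`` seeded starts (random mixing, a Boltzmann-weight
    guess, and perturbations thereof) and returns the best feasible
    solution; deterministic given ``spec.seed``.  Non-convergence is
    flagged on the result, never silent.
    """
    space = StateSpace(spec.specs, sphere=spec.sphere)
    comp = spec.composition
    sys = _ReducedSystem(space, comp, spec.table)

    rng = np.random.default_rng(spec.seed)
    iu = np.triu_indices(sys.n)
    starts: list[np.ndarray] = [np.zeros(sys.n_free)]
    # quasichemical-style guess: pair weights Boltzmann in the contact energy
    starts.append(-sys.eps[iu])
    while len(starts) < max(spec.restarts, 1):
        scale = 0.5 * (1 + len(starts))
        base = starts[1] if len(starts) % 2 else starts[0]
        starts.append(base + rng.normal(scale=scale, size=sys.n_free))
    starts = starts[: max(spec.restarts, 1)]
    if warm_start is not None and len(warm_start) == sys.n_free:
        starts.insert(0, np.asarray(warm_start, dtype=float))

    best = None
    for k, w0 in enumerate(starts):
        res = scipy.optimize.minimize(
            sys.objective,
            w0,
            method="L-BFGS-B",
            options={
                "maxiter": spec.max_iter,
                "ftol": 1e-14,
                "gtol": max(spec.tol, 1e-12),
            },
        )
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else float("nan")
        cand = (float(res.fun), k, res, gnorm)
        if best is None or cand[0] < best[0]:
            best = cand
    assert best is not None
    fun, k_best, res, gnorm = best

    v_active, sinkhorn_ok = sys.v_from_w(res.x)
    A, U, S = sys.evaluate(v_active)
    pairs = PairTable(space, comp, sys.expand_v(v_active))
    converged = bool(sinkhorn_ok and np.isfinite(A) and (res.success or gnorm < 1e-5))
    if not spec.mixing_reference:
        a_mix = float("nan")
    elif comp.x1 <= _XTINY or comp.x1 >= 1 - _XTINY:
        a_mix = 0.0  # pure endpoint is its own reference
    else:
        a_mix = A - _pure_reference(spec)
    thermo = ThermoPoint(
        S, U, A, a_mix,
        converged=converged,
        n_iterations=int(res.nit),
        grad_norm=gnorm,
        restart_index=k_best,
    )
    return EquilibriumResult(spec, space, thermo, pairs, res.x)


def solve_curve(
    spec: SolveSpec,
    x_grid: Sequence[float],
    omega_grid: Sequence[float],
) -> pd.DataFrame:
    """Equilibrium state functions over a composition x omega grid.

    Returns a tidy frame (x1, omega, S, U, A, A_mix, converged, ...); each
    omega sweep is warm-started along x for curve continuity.
    """
    rows = []
    for omega in omega_grid:
        table = table_from_interchange(omega)
        warm = None
        for x1 in x_grid:
            s = replace(spec, table=table, composition=Composition(float(x1)))
            result = solve_equilibrium(s, warm_start=warm)
            warm = result.w
            t = result.thermo
            rows.append(
                {
                    "x1": float(x1),
                    "omega": float(omega),
                    "S": t.S_per_NkB,
                    "U": t.U_per_NkBT,
                    "A": t.A_per_NkBT,
                    "A_mix": t.A_mix_per_NkBT,
                    "converged": t.converged,
                    "iterations": t.n_iterations,
                    "grad_norm": t.grad_norm,
                    "restart": t.restart_index,
                }
            )
    return pd.DataFrame(rows)


def gibbs_helmholtz_check(
    spec: SolveSpec, scale_grid: Sequence[float]
) -> pd.DataFrame:
    """Thermodynamic-consistency check d A(s)/ds = U(s)/s.

    The interaction table is multiplied by a coupling scale s (the role of
    an inverse temperature); by the envelope theorem the derivative of the
    minimized dimensionless free energy with respect to s equals the mean
    unscaled cluster energy, i.e. U(s)/s.  Central differences at interior
    grid points are compared against the solved U.
    """
    scales = np.asarray(sorted(scale_grid), dtype=float)
    if len(scales) < 3:
        raise ValueError("need at least three coupling scales")
    A = np.empty_like(scales)
    U = np.empty_like(scales)
    warm = None
    for i, s in enumerate(scales):
        res = solve_equilibrium(
            replace(spec, table=spec.table.scaled(float(s)), mixing_reference=False),
            warm_start=warm,
        )
        warm = res.w
        A[i] = res.thermo.A_per_NkBT
        U[i] = res.thermo.U_per_NkBT
    dA = np.gradient(A, scales)
    u0 = np.where(scales != 0, U / np.where(scales == 0, 1.0, scales), np.nan)
    rows = pd.DataFrame(
        {
            "scale": scales,
            "A": A,
            "U": U,
            "dA_dscale": dA,
            "U_over_scale": u0,
        }
    )
    interior = rows.iloc[1:-1]
    denom = np.abs(interior["U_over_scale"]).replace(0.0, np.nan)
    rows["rel_mismatch"] = np.nan
    rows.loc[interior.index, "rel_mismatch"] = (
        np.abs(interior["dA_dscale"] - interior["U_over_scale"]) / denom
    )
    return rows


class DiceMixtureModel:
    """Two-component dice mixture on a simple cubic lattice.

    The statsmodels-style entry point: construct the model from molecule
    specifications (or built-in names), an interaction table or interchange
    energy, and a composition; :meth:`fit` minimizes the Helmholtz free
    energy and returns an :class:`EquilibriumResult`.

    Parameters
    ----------
    component1, component2 : MoleculeSpec or str
        Molecule specs, or built-in names ("angled", "stretched", "inert").
    x1 : float
        Molar fraction of component 1.
    table : InteractionTable, optional
        Contact energies per k_B·T.  Alternatively give ``omega``.
    omega : float, optional
        Dimensionless interchange energy; expands to the symmetric
        like-repels/unlike-attracts pattern.
    sphere : bool
        Collapse orientations (orientation-free mixing limit).

    Examples
    --------
    >>> m = DiceMixtureModel("angled", "inert", x1=0.5, omega=-1.0)
    >>> res = m.fit(seed=0)
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(
        self,
        component1: MoleculeSpec | str,
        component2: MoleculeSpec | str | None = None,
        *,
        x1: float = 0.5,
        table: InteractionTable | None = None,
        omega: float | None = None,
        sphere: bool = False,
    ):
        if isinstance(component1, str):
            component1 = builtin_molecule(component1, component_id=1)
        if isinstance(component2, str):
            component2 = builtin_molecule(component2, component_id=2)
        if component2 is not None and component2.component_id == component1.component_id:
            component2 = component2.with_component_id(component1.component_id + 1)
        if (table is None) == (omega is None):
            raise ValueError("give exactly one of `table` or `omega`")
        if table is None:
            table = table_from_interchange(float(omega))
        specs = (component1,) if component2 is None else (component1, component2)
        self.spec = SolveSpec(
            specs=specs,
            table=table,
            composition=Composition(float(x1)),
            sphere=sphere,
        )

    def fit(
        self,
        *,
        seed: int = 0,
        restarts: int = 5,
        tol: float = 1e-10,
        max_iter: int = 1000,
        mixing_reference: bool = True,
    ) -> EquilibriumResult:
        spec = replace(
            self.spec,
            seed=seed,
            restarts=restarts,
            tol=tol,
            max_iter=max_iter,
            mixing_reference=mixing_reference,
        )
        return solve_equilibrium(spec)

    def random_mixing(self) -> ThermoPoint:
        return random_mixing_point(self.spec)

    def curve(self, x_grid: Sequence[float], omega_grid: Sequence[float],
              **fit_kwargs) -> pd.DataFrame:
        spec = replace(self.spec, **fit_kwargs) if fit_kwargs else self.spec
        return solve_curve(spec, x_grid, omega_grid)
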