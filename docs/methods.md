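# Methods

## The model

`dicelattice` treats a binary liquid mixture as a fully occupied simple
cubic lattice of six-sided dice.  A molecule state is a (component,
orientation) pair; orientations are the 24 proper rotations of the cube,
represented as permutations of the six axis directions (body frame → lab
frame).  The modelling unit is the four-molecule cluster: a central die A
with neighbors B, C, D along +x, +y, +z.  The sign convention for the three
bonds is immaterial by isotropy; the positive octant is fixed once in
`geometry.CLUSTER_TOPOLOGY`.

The lattice is imagined as built sequentially, one molecule inserted into
an existing three-neighbor environment.  This makes the entropy per
molecule the conditional Shannon entropy of the inserted state given the
neighborhood,

    S/(N k_B) = − Σ p_abcd ln(p_abcd / p_bcd),   p_bcd = Σ_a p_abcd,

which obeys the chain rule S_cluster = S_neighborhood + S_system for any
distribution (property-tested).  The internal energy per molecule is the
mean cluster energy, where e_abcd is the sum of the three contact energies
ε(class of A's facing face, class of neighbor's facing face) — three bonds
per molecule, matching the 3L³ bonds of the lattice.  Equilibrium minimizes
A/(N k_B T) = U/(N k_B T) − S/(N k_B) at fixed temperature and composition;
temperature never appears separately because all energies are dimensionless
per k_B T, and coupling sweeps scale the table (a scale factor plays the
role of an inverse temperature).

### Constraints and the reduced variables

The full variable set — one probability per cluster state, (2·24)⁴ of them
plus the target — is never optimized directly.  Three structural reductions
implement the model's constraints:

1. **Composition marginals**: p_a = x_i/24 for every state of component i.
2. **Isotropy**: the three views of one cluster under the 120° rotation
   about the cube diagonal are the same cluster.  One conditional pair
   table serves all three bond axes; the explicit equal-probability
   conditions this replaces (2/3 · 48⁴ = 3,538,944) are still counted by
   enumeration, and the equality of class members' probabilities and
   energies is asserted post hoc.
3. **Contact-class equivalence**: the conditional probability of a neighbor
   state depends only on the components and site classes of the two
   touching faces.  Site types are (component, face class); each type
   groups 4 orientations per face of that class.

The free variables are the symmetric joint contact-pair probabilities
η[s,t] (central type s touching neighbor type t), with row sums pinned to
the single-state probabilities: Σ_t n_t η[s,t] = p0_s.  In the general
two-component case that is 78 symmetric entries minus 12 per-site
normalizations = 66 free variables.  Positivity and the row constraints are
structural: η = diag(λ)·K·diag(λ) with K = exp(w) symmetric and λ the
symmetric Sinkhorn scaling to the prescribed row sums (tolerance 1e-14,
≤ 5000 iterations).  Diagonal rescalings of K are absorbed by λ, so the
effective dimension is exactly the free count; the random-mixing solution
(neighbor independent of centre, p_{b|a} = p_b) is w = 0 exactly, which is
why the zero-coupling solver reproduces S = ln 24 − Σ x ln x to machine
precision.

The objective is evaluated on the contact-class level: cluster terms depend
on the neighbors only through their contact types, so the 48⁴ sums collapse
to (central group) × (neighbor type)³ arrays of a few thousand entries.
The full 48⁴ path (`cluster.energies_4d`, `cluster.system_entropy`, …)
is retained as the brute-force oracle; expanding a reduced solution and
evaluating it directly agrees with the reduced path to ~1e-15.

### Solver

`scipy.optimize.minimize(method="L-BFGS-B")` over w with finite-difference
gradients; ftol 1e-14.  Starts: w = 0 (random mixing), a quasichemical
Boltzmann guess w = −ε, and seeded Gaussian perturbations of both (default
5 restarts; curves also warm-start from the neighboring grid point).  The
best restart is reported with iteration count, gradient norm and restart
index; non-convergence is flagged, never silent.  Compositions within
1e-12 of 0 or 1 drop the absent component's site types entirely, so pure
endpoints are exact.  Probabilities below 1e-15 are treated as exact zeros
in entropy terms (0·ln 0 = 0).

Two free energies are reported: the full A/(N k_B T), which contains the
orientational entropy −ln 24, and a mixing-referenced A_mix with the
x-weighted pure-component free energies subtracted (pure components are
solved with the same machinery; for interacting molecules such as Angled
the pure reference is itself below −ln 24).

## The Monte-Carlo benchmark

A Metropolis simulation of the same dice on a periodic L×L×L lattice.
Periodic boundaries are chosen for bulk behaviour; the move set is a 50/50
mix (configurable) of single-site re-orientations and two-site content
swaps, the latter required to sample the canonical fixed-composition
ensemble.  ΔE is computed from affected bonds only, with explicit
correction of the bonds shared between swapped sites (including the L = 2
double-wrap case); a drift test checks the running total against full
recomputation after 10⁴ steps to 1e-9.  Acceptance is min(1, exp(−β̂ΔE))
with β̂ scaling the dimensionless table.  One sweep is L³ attempted moves.

Detailed balance is verified on a 2×2×2 sphere-mode lattice by comparing
visit frequencies of all C(8,4) = 70 fixed-composition configurations
against exact Boltzmann weights (χ² test on thinned samples).

Free energies come from Gibbs–Helmholtz integration: with U₀(β̂) the
sampled mean unscaled bond energy per molecule, d(A/N k_B T)/dβ̂ = U₀,
integrated by the trapezoidal rule from the exact infinite-temperature
reference A₀/(N k_B T) = Σ x_i ln x_i − ln 24.  Sampling errors
(block averages, ≥ 10 blocks) propagate through the quadrature.  The same
identity is checked model-side by central differences of A(β̂) against
U/β̂ (envelope theorem), and by integrating model-generated U series.

## Problem sizes and defaults

- Equilibrium solves: exact reduced systems; seconds per point.
- Benchmark runs: L = 10 (1000 sites) with a 12-point β̂ grid from 0 to 1,
  300 equilibration and 1500 sampling sweeps per point, annealed along the
  schedule.  These sizes give free-energy standard errors of order 1e-5 at
  ω = −1, far below the model-vs-MC deviations of interest; L and sweep
  counts are configurable for production-scale runs (e.g. L = 30).
- Bookkeeping counts are produced by explicit enumeration over the 48⁴
  cluster space (vectorized orbit counting; the state count itself by
  literal iteration).

## What the built-in examples do and do not show

The Angled/Stretched/Inert molecules with the symmetric
like-repels/unlike-attracts interaction pattern (ε11 = ε22 = −ω/4,
ε12 = ε21 = +ω/4, class 0 inert) probe exactly one physical effect:
geometric isomer distinction under increasing unlike attraction.  At
ω₁₂/k_BT = −1 both isomer mixtures are indistinguishable from each other
and close to random mixing; the free-energy gap grows as the attraction
strengthens, and from around ω = −12 the Stretched mixture drops clearly
below the Angled one at high interacting-component fraction (chain
ordering through the two opposite interacting faces).  In the pre-onset
region −4 … −10 the model places Angled marginally lower (|ΔA| ≲ 4e-3);
the distinguishing signal is the pronounced post-onset separation, not the
tiny pre-onset one.  Passing tests on these dice say nothing about real
molecules: mapping real interaction energies onto face classes
(force-field or quantum-chemical parameterization) is out of scope.

## Known limitations

- Exactly two components; equal-sized molecules; no vacancies, so volume
  is not a variable.  Long-chain/size-asymmetric molecules are outside the
  model.
- Nearest-neighbor contacts only; no long-range or next-nearest-neighbor
  terms.
- The pair factorization p_abcd = p_a p_{b|a} p_{c|a} p_{d|a} is an
  approximation: neighbors are conditionally independent given the centre,
  so closed loops of correlation are truncated.  Deviations from the MC
  benchmark therefore grow with coupling strength.
- The symmetric η parameterization fixes only the A-position marginals at
  the composition; the B/C/D marginals follow from symmetry of η rather
  than being constrained separately.
- Finite-difference gradients limit practical solver tolerances to ~1e-7
  in the gradient norm; reported free energies are nevertheless stable to
  ~1e-9 across restarts because the objective is evaluated analytically.
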