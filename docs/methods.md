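# Methods

## Model and state spaces

The system is a closed reaction network over food X, waste W and a
protocell population U distributed on the trait rectangle
D = [−1, 1] × [0, L]: replication `X + U → U + U′` (offspring traits drawn
from a mutation density centered on the parent), decay `U → W`, and
recycling `W → X`.  Because every reaction moves one unit between the
three pools, the total matter ρ₀ is an invariant; both integrators are
built so the invariant survives discretization exactly (see below).
A pass-through variant (constant food inflow, waste discarded) would lack
this invariant and is not implemented.

Two state representations coexist:

* **RealState** — concentrations, normalized so the conserved total is 1.
  On this scale the rate constant k₀ applies directly.
* **IntState** — integer molecule counts summing to ρ₀.  Rates are scaled
  by 1/ρ₀ⁿ so that concentrations ≡ counts/ρ₀ obey the same law.

The stoichiometry exponent n (n food molecules needed simultaneously) is
supported as a birth-propensity exponent and by the printed factor n in the
reduced food equation; only n = 1 has the exact conservation contract, and
all shipped scenarios use n = 1.

## Discretization

The grid is node-centered and includes the domain boundary, so the
homochiral states η = ±1 — where the stationary peak lives — are grid
points.  η nodes are generated as (2i − (d−1))/(d−1), which makes the
mirror identity η_i = −η_{d−1−i} hold bitwise; several evenness
invariants (k_a symmetry, mirrored fitness maxima at g = 0) are then exact
rather than approximate.  Double integrals use trapezoidal weights
(halved on edges, quartered at corners), which reproduce the domain area
2L to rounding error and make the discrete kernel-column normalization
consistent with the continuum normalization of the mutation density.

The mutation density is a product of one-dimensional truncated normals
with erf edge normalization.  Its discretization exploits separability:
one mass matrix per axis (density × weight, columns normalized to 1),
combined by a Kronecker product.  Sparsification zeroes combined per-node
masses below the threshold z and renormalizes each source column to 1, so
the kernel is exactly column-stochastic — no protocell mass is created or
lost by placement.  The threshold is applied to the discrete *mass*, not
the density; with the reference values (d = 500, ε = 0.01, z = 10⁻⁵) an
interior source keeps 15 of 250,000 targets, which is what makes the
dynamics tractable.  Entries below z are dropped from the 1-D factors
first; this is exact because the complementary factor never exceeds 1.

Worth noting: at the full-size resolution the ζ spacing (25/499 ≈ 0.05) is
several times larger than the reference mutation scales ε_ζ = 0.005–0.01,
so the thresholded ζ factor collapses onto the source column and the
discrete dynamics cannot move along the information axis at those exact
values.  The scaled test scenarios in this repository therefore choose
ε (or the grid) so that the mutation scale is resolved whenever an axis is
meant to evolve, and treat sub-resolution ε as a deliberate way to freeze
an axis.

## Dynamics

**Euler stepping (concentrations).**  Birth mass per source is
k₀ ρ_Xⁿ k_a U w, routed to targets through the sparse placement matrix;
deaths move γ₀ γ U to waste; recycling moves s ρ_W to food.  Each transfer
is debited and credited pairwise, so conservation is exact up to float
rounding.  Negative overshoots (the known failure mode of explicit
stepping on stiff decay) are clamped to zero and the clamped mass is
debited from the food pool, preserving the invariant through clamping.
Implicit or higher-order integrators are intentionally absent: at d² state
variables they would require prohibitive linear algebra, and the
continuum representation is anyway superseded by the integer stepper for
long runs, where round-off noise in empty regions would otherwise be
amplified exponentially into spurious colonies.

**Tau-leaping (integer counts).**  One leap of length Δt = 1 epoch draws
Poisson counts for every reaction channel with propensities frozen at the
leap start.  Births are drawn per nonzero kernel entry
(mean (k₀/ρ₀ⁿ) N_Xⁿ k_a(src) N_U(src) m(tgt|src) Δt); this is equivalent
in law to drawing a per-source total and splitting it multinomially, but
vectorizes into a single generator call.  If the drawn births exceed the
food present they are thinned uniformly at random (multivariate
hypergeometric over the drawn events) to consume exactly N_X — the leap is
adjusted by discarding events, not by shortening Δt.  Death counts are
clamped to the protocells present; the clamped difference is charged
against the death channel, so N_X + N_W + ΣN_U = ρ₀ holds exactly at every
step, and the stepper asserts it.

Randomness is consumed in a canonical node order carried by the kernel's
orientation flag.  Mirroring a kernel (η → −η) flips the flag, so a run
driven by the mirrored kernel replays the same random stream against the
mirrored propensities and reproduces the mirrored trajectory bit-for-bit —
a strong check that no hidden chiral bias leaks in through the
implementation.

## Stationary analysis

The stationary shape solves the eigenproblem of the operator
v ↦ (1/γ) ∬ k_a p v, discretized with quadrature weights.  The leading
eigenpair is found by power iteration from a uniform positive vector
(guaranteed overlap with the nonnegative leading mode), renormalized in
the weighted L2 norm; convergence is declared when the Rayleigh-quotient
eigenvalue estimate changes by ≤ tol (default 10⁻¹⁰, max 10⁵ sweeps).
Dense eigendecomposition is avoided deliberately (the operator is d² × d²).
For small mutation scales the eigenvalue approaches max k_a/γ and the
eigenvector peaks at its argmax; with the reference parameters that is
η = 1, ζ ≈ 20.3 — the point where the x⁸ decay penalty overtakes the
quadratic replication gain.  Near-degenerate spectra (neighboring nodes
with nearly equal fitness) make the iteration slow but do not affect the
eigenvalue at the tolerances used.

## Convection–diffusion reading

The six moment integrals of k_a p (creation α, drift β, diffusion δ) are
evaluated per node as sparse row sums of the discrete kernel, and
separately in their small-ε closed forms (α ≈ r k_a, β ≈ (r/2)∇k_a ε²,
δ_diag ≈ (r/2) k_a ε², with analytic derivatives of the separable k_a).
Two numerical caveats shape the tests:

* the exact cross-diffusion δ_ηζ is not zero but O(ε⁴) — of order
  β_η β_ζ / r, about 10⁻⁵ of the diagonal entries at ε = 0.01 — and
  vanishes exactly on the η = 0 axis;
* comparisons are made on the interior (deeper than 6ε from the edges),
  where the truncated normal is indistinguishable from a free normal, and
  on grids with spacing ≤ ε: trapezoidal sums of Gaussians are spectrally
  accurate down to spacing ≈ ε, and degrade abruptly below that.

## Scaled study conditions

The reference configuration (d = 500, ρ₀ = 10¹⁸, t = 2·10⁵) is far beyond
a test budget; the stochastic phenomenology is reproduced at desk scale
with conditions chosen once, on dimensional grounds, before the assertions
were frozen:

* **Euler limit**: ρ₀ = 10¹² with the initial population scaled to the
  same concentration (U₀₀/ρ₀ = 10⁻³), 20 × 20 grid, 100 steps, 20 seeds.
* **Diffusive width law**: neutral flat-fitness configuration
  (b_η = b_ζ = a_ζ = f = g = 0, so α ≡ γ after the food settles), d = 101,
  γ₀ = 0.1 and k₀ = 1 so the diffusive stage dominates within ~10³ steps,
  ε_η ∈ {0.04, 0.02} with ε_ζ sub-resolution (ζ frozen, keeping the check
  one-dimensional), ρ₀ = 10⁸.  Widths are compared at (ε, T) vs
  (ε/2, 4T); the common stage-1 prefix, which does not rescale, biases the
  ratio by a few percent and is well inside the 10% band.
* **Symmetry breaking**: η-only scenario (b_ζ = f = 0, ζ frozen), strong
  mutation ε_η = 0.15 and fast turnover γ₀ = 0.25, k₀ = 1, T = 1500.  With
  g = 0.02 resolvable on the d = 100 grid and ρ₀ = 10⁹ the final mean
  excess is positive essentially always; with g = 0 at ρ₀ = 10⁶ on a
  centered (odd-d) grid the final sign is seed-dependent.  The even
  d = 100 grid has no η = 0 node — its origin node sits half a cell to the
  negative side — so the directed check runs against a slightly adverse
  initial placement, and the undirected check uses an odd grid to avoid
  that spurious bias.

What the generator does not emulate: real mutational processes are neither
Gaussian nor trait-independent, the fitness forms are quadratic toys, and
the closed recycling loop has no spatial structure or thermodynamic cost.
Passing tests therefore validate the numerics and the internal logic of
the model — exact conservation, correct limits, the predicted stage
structure and peak locations — not any claim about prebiotic chemistry.

## Known limitations

* n > 1 lacks an exact conservation contract (the full-grid bookkeeping
  for simultaneous food consumption is not defined by the model equations
  as printed); the reduced three-variable system is the supported route.
* Stage segmentation is a heuristic on the food curve (threshold relative
  to the steepest drop, minimum run length); boundaries are indicative,
  configurable, and not comparable across very different parameter sets.
* The stationary solver returns only the leading eigenpair; subleading
  modes (metastable species mixtures) are out of scope.
* At very small g (≲ one grid cell of η resolution) the direction of
  symmetry breaking is grid-limited, mirroring the physical statement that
  an unresolved bias cannot direct the outcome.
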