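# protocells

Simulation and analysis of protocell evolution in a two-dimensional trait
space: **enantiomeric excess** η ∈ [−1, 1] (how strongly the cell's
chemistry prefers one mirror-image molecular form; 0 is racemic, ±1 is
homochiral) and **inherited information** ζ ∈ [0, L] (the natural log of
the bits a cell passes to its offspring).  The package is for researchers
studying the origin of homochirality and of heredity: it lets you ask how a
nearly racemic, information-poor founding population evolves toward the
homochiral, information-rich stationary state, and whether the direction of
symmetry breaking is set by a small physical bias or by chance.

## Model

A closed system holds a fixed total of ρ₀ "molecules" partitioned into food
X, waste W, and protocells U(η, ζ).  Three reactions drive it:

    X + U  →  U + U′        replication with a small trait mutation
    U      →  W             decay
    W      →  X             recycling

so ρ_X + ρ_W + ∬U dη dζ is an exact invariant.  Replication is governed by
the kernel K(η, ζ | η′, ζ′) = k₀ · k_a(η′, ζ′) · p(η, ζ | η′, ζ′), where

* k_a = (1 + b_η η²/2)(1 + a_ζ x + b_ζ x²/2), x = cζ, is the replication
  advantage (even in η by L/D symmetry);
* p is a product of truncated normals of scale ε_η, ε_ζ centered on the
  parent's traits (erf-normalized at the domain edges);
* decay runs at γ₀ · γ with γ = (1 − gη)(1 + f x⁸/8!): the small factor g
  is the global chiral bias, and f caps the information load.

The mean-field dynamics are

    dU/dt = ρ_X ∬ K U′ dη′ dζ′ − γ₀ γ U,

run either as forward-Euler stepping in concentrations, or — because the
continuum description amplifies round-off noise into spurious colonies —
as integer-count tau-leaping (Poisson reaction counts per step, births
thinned to the available food, counts conserved exactly).  The stationary
distribution is the leading eigenvector of the Fredholm operator
k_a p / γ, with eigenvalue λ ≈ max k_a/γ locating the stationary peak; a
convection–diffusion expansion gives the drift β ∝ ∇k_a ε² and diffusion
δ ∝ k_a ε²/2 that shape the intermediate stages.

## Worked example

```python
import protocells as pc

params = pc.ModelParams(eps_eta=0.2, eps_zeta=1.5, rho0=10**6, seed=0)
grid = pc.build_grid(20, params.L)
kernel = pc.build_sparse_kernel(grid, params)

eta0, zeta0, fmax = pc.fitness_argmax(params)
print(f"fitness peak: eta0={eta0:.3f}, zeta0={zeta0:.3f}, ka/gamma={fmax:.3f}")

res = pc.leading_eigenpair(kernel)
print(f"leading eigenvalue lambda={res.lam:.4f}, stationary food rho_X*={res.rho_X_star:.4f}")

traj = pc.run_simulation(grid, params, T_max=2000, stats_every=10, kernel=kernel)
last = traj.series[-1]
print(f"t={last.t:.0f}: U0={last.U0:.0f} protocells, mu_eta={last.mu_eta:.3f}, "
      f"mu_zeta={last.mu_zeta:.2f}, food={last.food_frac:.2f}%")
print("stage boundaries:", traj.stage_bounds)
```

prints

```
fitness peak: eta0=1.000, zeta0=20.275, ka/gamma=2.337
leading eigenvalue lambda=1.8612, stationary food rho_X*=0.0537
t=2000: U0=931332 protocells, mu_eta=-0.108, mu_zeta=14.86, food=5.84%
stage boundaries: [130]
```

Reading the output: the fitness map k_a/γ peaks at the homochiral edge
η = 1 (thanks to g > 0) and at ζ ≈ 20.3, where the x⁸ penalty in γ
overtakes the quadratic gain in k_a — the predicted stationary state.  The
leading eigenvalue sits below the fitness maximum because this coarse
kernel mutates aggressively (ε_η = 0.2).  After 2000 epochs the stochastic
run has consumed the food down to ~6% of all matter (the population holds
most of the rest), the distribution has drifted up the information axis
(μ_ζ ≈ 15) but has not yet broken chiral symmetry (μ_η ≈ −0.1), and the
food-curve segmentation puts the end of the initial exponential stage at
t ≈ 130.

A command-line interface wraps the same operations
(`protocells simulate|stationary|diffusion|stages|fixtures`); four shipped
scenario configs `model_a` … `model_d` encode the reference model variants
(a_ζ ∈ {0, 1} × ε ∈ {0.005, 0.01}).

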