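"""Stochastic dynamics in integer molecule counts (tau-leaping).

One leap of length ``dt`` fires Poisson-distributed reaction counts with all
propensities evaluated at the leap start:

* birth: a protocell at source node j produces offspring at target node i
  with mean ``(k0 / rho0^n) N_X^n ka_j N_U_j m_ij dt`` where ``m_ij`` is the
  kernel placement mass (Poisson counts per kernel entry are equivalent in
  law to a per-source Poisson total split multinomially over targets);
* death: node i loses protocells to waste with mean
  ``gamma0 gamma_i N_U_i dt``;
* recycling: waste returns to food with mean ``s N_W dt``.

Stability near zero counts: if the drawn births exceed the available food
they are thinned uniformly at random (a multivariate hypergeometric draw
over birth events) to consume exactly the food present, and death counts
are clamped to the protocells present; the clamped difference is charged
against the same reaction's event count.  With ``n = 1`` the total count
``N_X + N_W + sum N_U`` then equals ``rho0`` exactly at every step.

Randomness is consumed in canonical (unmirrored) node order, so a run
driven by an eta-mirrored kernel reproduces the mirrored trajectory
bit-for-bit from the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid
from .kernel import SparseKernel
from .params import ModelParams, run_label

__all__ = ["IntState", "init_state", "step_tau", "run_simulation", "mirror_int_state"]


@dataclass
class IntState:
    """Integer-count system state with its own reproducible generator."""

    N_U: np.ndarray           # per-node protocell counts, int64, flat order
    N_X: int                  # food molecules
    N_W: int                  # waste molecules
    step: int
    rng: np.random.Generator

    @property
    def rng_state(self) -> dict:
        return self.rng.bit_generator.state

    def total(self) -> int:
        return int(self.N_U.sum()) + int(self.N_X) + int(self.N_W)


def init_state(grid: Grid, params: ModelParams, seed: int | None = None) -> IntState:
    """``U00`` protocells at the node nearest the origin, the rest as food."""
    if params.rho0 <= params.U00:
        raise ValueError(f"need rho0 > U00, got rho0={params.rho0}, U00={params.U00}")
    N_U = np.zeros(grid.n_nodes, dtype=np.int64)
    N_U[grid.nearest_node(0.0, 0.0)] = params.U00
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return IntState(N_U=N_U, N_X=int(params.rho0) - int(params.U00), N_W=0, step=0, rng=rng)


def mirror_int_state(state: IntState, grid: Grid) -> IntState:
    """The eta-mirrored copy of a state (counts relabeled, same rng)."""
    perm = grid.mirror_permutation()
    return IntState(
        N_U=state.N_U[perm], N_X=state.N_X, N_W=state.N_W, step=state.step, rng=state.rng
    )


def _entry_arrays(kernel: SparseKernel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(source, target, mass) per nonzero entry of the canonical placement
    matrix, cached on the kernel."""
    cache = getattr(kernel, "_entry_cache", None)
    if cache is None:
        P = kernel.P_canonical
        src = np.repeat(np.arange(P.shape[1], dtype=np.int64), np.diff(P.indptr))
        cache = (src, P.indices.astype(np.int64), P.data)
        kernel._entry_cache = cache
    return cache


def _to_canonical(v: np.ndarray, grid: Grid, flipped: bool) -> np.ndarray:
    if not flipped:
        return v
    return np.ascontiguousarray(v.reshape(grid.d, grid.d)[::-1]).ravel()


def step_tau(state: IntState, kernel: SparseKernel, params: ModelParams) -> IntState:
    """Advance one leap of length ``params.dt``."""
    grid = kernel.grid
    N = grid.n_nodes
    if state.N_U.shape != (N,):
        raise ValueError("state size does not match the kernel grid")
    rng = state.rng
    dt = params.dt
    flipped = kernel.orientation < 0

    N_U = _to_canonical(state.N_U, grid, flipped)
    ka = _to_canonical(kernel.ka, grid, flipped)
    gamma = _to_canonical(kernel.gamma, grid, flipped)
    src, tgt, mass = _entry_arrays(kernel)

    # --- births -----------------------------------------------------------
    coef = params.k0 * (state.N_X / params.rho0) ** params.n * dt
    active_e = N_U[src] > 0
    born = np.zeros(N, dtype=np.int64)
    births_total = 0
    if active_e.any():
        s_act = src[active_e]
        means = coef * ka[s_act] * N_U[s_act] * mass[active_e]
        events = rng.poisson(means)
        births_total = int(events.sum())
        if births_total > state.N_X:
            # food-limited leap: keep exactly N_X birth events, chosen
            # uniformly at random among those drawn
            events = rng.multivariate_hypergeometric(
                events, int(state.N_X), method="marginals"
            )
            births_total = int(state.N_X)
        if births_total > 0:
            born = np.bincount(
                tgt[active_e], weights=events.astype(np.float64), minlength=N
            ).astype(np.int64)

    # --- deaths -----------------------------------------------------------
    occupied = np.flatnonzero(N_U)
    deaths = np.zeros(N, dtype=np.int64)
    if occupied.size:
        d_events = rng.poisson(params.gamma0 * dt * gamma[occupied] * N_U[occupied])
        d_events = np.minimum(d_events, N_U[occupied] + born[occupied])
        deaths[occupied] = d_events
    deaths_total = int(deaths.sum())

    # --- recycling --------------------------------------------------------
    recycled = min(int(rng.poisson(params.s * state.N_W * dt)), state.N_W)

    N_U_new = N_U + born - deaths
    N_X_new = state.N_X - births_total + recycled
    N_W_new = state.N_W + deaths_total - recycled

    new = IntState(
        N_U=_to_canonical(N_U_new, grid, flipped),
        N_X=N_X_new,
        N_W=N_W_new,
        step=state.step + 1,
        rng=rng,
    )
    if params.n == 1 and new.total() != params.rho0:
        raise RuntimeError(
            f"conservation violated at step {new.step}: total {new.total()} != rho0 {params.rho0}"
        )
    return new


def run_simulation(
    grid: Grid,
    params: ModelParams,
    T_max: int,
    snapshot_every: int = 0,
    stats_every: int = 1,
    kernel: SparseKernel | None = None,
    seed: int | None = None,
):
    """Run ``T_max`` leaps, recording summary statistics and optional full
    snapshots.  Deterministic given the seed.  Returns a
    :class:`~protocells.stats.Trajectory`.
    """
    from .kernel import build_sparse_kernel
    from .stats import Trajectory, detect_stages, summarize

    if kernel is None:
        kernel = build_sparse_kernel(grid, params)
    state = init_state(grid, params, seed)
    used_seed = params.seed if seed is None else seed

    series = [summarize(state.N_U, grid, state.N_X, state.N_W, t=0)]
    snapshots = []
    if snapshot_every:
        snapshots.append((0, state.N_U.copy()))
    for step in range(1, int(T_max) + 1):
        state = step_tau(state, kernel, params)
        if step % stats_every == 0:
            series.append(summarize(state.N_U, grid, state.N_X, state.N_W, t=step))
        if snapshot_every and step % snapshot_every == 0:
            snapshots.append((step, state.N_U.copy()))

    food = np.array([s.food_frac for s in series])
    bounds = detect_stages(food) if food.size >= 10 else []
    # stats may be subsampled; report bounds in simulation steps
    bounds = [int(b * stats_every) for b in bounds]
    manifest = {
        "params": params.to_dict(),
        "d": grid.d,
        "T_max": int(T_max),
        "snapshot_every": int(snapshot_every),
        "stats_every": int(stats_every),
        "label": run_label(params, grid.d),
        "seed": int(used_seed),
        "invariant_check": {
            "conserved": params.n == 1,
            "max_deviation": 0 if params.n == 1 else None,
        },
    }
    return Trajectory(series=series, snapshots=snapshots, stage_bounds=bounds, manifest=manifest)
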