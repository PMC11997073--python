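"""Deterministic (real-valued) dynamics of the closed protocell model.

Forward-Euler stepping of the integrodifferential system: protocells
replicate at rate ``k0 * rho_X * ka`` with offspring placed through the
mutation kernel, die at rate ``gamma0 * gamma`` into waste, and waste is
recycled back to food at rate ``s``.  The total matter
``rho_X + rho_W + integral U`` is conserved exactly by construction; any
negative overshoot is clamped to zero with the clamped mass debited from the
food pool so the invariant survives clamping.

Also provides the delta-peak reduced system (population still concentrated
at the origin) and the stage-1 duration estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import Grid
from .kernel import SparseKernel
from .params import ModelParams

__all__ = [
    "RealState",
    "NoGrowthError",
    "init_real_state",
    "step_euler",
    "reduced_ode_step",
    "estimate_t0",
]


class NoGrowthError(ValueError):
    """Initial conditions admit no exponential growth (k0 rho_X <= gamma0)."""


@dataclass
class RealState:
    """Concentration-valued system state.

    ``U`` is the per-node protocell concentration (flat eta-major order);
    integrals over the trait space use the grid quadrature weights.
    """

    U: np.ndarray
    rho_X: float
    rho_W: float
    t: float = 0.0

    def total(self, grid: Grid) -> float:
        return self.rho_X + self.rho_W + float(self.U @ grid.cell_weight)


def init_real_state(grid: Grid, params: ModelParams) -> RealState:
    """All protocell mass at the node nearest the origin, the rest as food.

    Concentrations are expressed in units of the total matter, so the
    conserved total is 1 and the initial population is ``U00 / rho0``; this
    is the scale on which ``k0`` applies directly (the integer-count stepper
    uses ``k0 / rho0^n`` instead).
    """
    U = np.zeros(grid.n_nodes)
    origin = grid.nearest_node(0.0, 0.0)
    u00 = params.U00 / params.rho0
    U[origin] = u00 / grid.cell_weight[origin]
    return RealState(U=U, rho_X=1.0 - u00, rho_W=0.0, t=0.0)


def step_euler(
    state: RealState, kernel: SparseKernel, params: ModelParams, dt: float | None = None
) -> RealState:
    """One forward-Euler step of the full-grid dynamics."""
    if dt is None:
        dt = params.dt
    grid = kernel.grid
    w = grid.cell_weight
    if state.U.shape != (grid.n_nodes,):
        raise ValueError(
            f"state has {state.U.shape[0] if state.U.ndim else '?'} nodes, "
            f"kernel grid has {grid.n_nodes}"
        )

    # total birth mass produced by each source node per unit time
    flux = params.k0 * state.rho_X**params.n * kernel.ka * state.U * w
    born = kernel.P @ flux                       # mass arriving at each target
    deaths = params.gamma0 * kernel.gamma * state.U

    U_new = state.U + dt * (born / w - deaths)
    born_total = dt * float(flux.sum())
    died_total = dt * float(deaths @ w)
    recycled = dt * params.s * state.rho_W

    rho_X = state.rho_X - born_total + recycled
    rho_W = state.rho_W - recycled + died_total

    neg = U_new < 0
    if neg.any():
        deficit = -float(U_new[neg] @ w[neg])
        U_new[neg] = 0.0
        rho_X -= deficit
    if rho_W < 0:  # recycling overshoot: hand the deficit to food
        rho_X += rho_W
        rho_W = 0.0
    if rho_X < 0:  # birth overshoot: charge waste
        rho_W += rho_X
        rho_X = 0.0
        if rho_W < 0:
            raise RuntimeError("dt too large: food and waste both exhausted below zero")
    return RealState(U=U_new, rho_X=rho_X, rho_W=rho_W, t=state.t + dt)


def reduced_ode_step(
    U0: float, rho_X: float, rho_W: float, params: ModelParams, dt: float | None = None
) -> tuple[float, float, float]:
    """Forward-Euler step of the delta-peak reduced system.

    Valid while the population remains a point mass at the origin, where
    ``ka = gamma = 1``.  The stoichiometry ``n`` multiplies the food
    equation only.
    """
    if dt is None:
        dt = params.dt
    if min(U0, rho_X, rho_W) < 0:
        raise ValueError("reduced state must be nonnegative")
    dU0 = (params.k0 * rho_X - params.gamma0) * U0
    dX = params.n * (-params.k0 * rho_X * U0 + params.s * rho_W)
    dW = -params.s * rho_W + params.gamma0 * U0
    return U0 + dt * dU0, rho_X + dt * dX, rho_W + dt * dW


def estimate_t0(rho_X0: float, U00: float, k0: float, gamma0: float) -> float:
    """Duration of the initial exponential stage:
    ``ln(rho_X0 / U00) / (k0 rho_X0 - gamma0)``.

    This is the time for ``U00`` protocells to grow to the order of the
    available food, after which growth is food-limited.
    """
    if not (rho_X0 >= U00 > 0):
        raise ValueError(f"need rho_X0 >= U00 > 0, got rho_X0={rho_X0}, U00={U00}")
    rate = k0 * rho_X0 - gamma0
    if rate <= 0:
        raise NoGrowthError(
            f"k0 * rho_X0 = {k0 * rho_X0} does not exceed gamma0 = {gamma0}: no growth"
        )
    return float(np.log(rho_X0 / U00) / rate)
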