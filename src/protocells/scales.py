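"""Physical readings of the model scales.

Small closed-form translations between model parameters and real-world
quantities: the geological upper bound on the initial growth stage, the mean
protocell lifespan implied by the decay rate, the information capacity of
the zeta axis, and the time rescaling that equalizes diffusive widths across
mutation rates.
"""

from __future__ import annotations

import math

from .dynamics_ode import estimate_t0

__all__ = [
    "stage1_years_bound",
    "mean_lifespan",
    "information_capacity_bytes",
    "diffusive_time_factor",
]


def stage1_years_bound(ln_cap: float = 100.0, efolds_per_year: float = 1.0) -> float:
    """Upper bound, in years, on the initial exponential stage.

    Capping the population logarithm ``ln(rho_X(0) / U00)`` at the number of
    organic molecules on Earth gives ``ln_cap`` of at most ~1e2; with a
    (deliberately slow) growth of one e-fold per year and negligible decay
    the stage lasts at most ``ln_cap / efolds_per_year`` years.
    """
    # estimate_t0 with k0 * rho_X0 = efolds_per_year and rho_X0/U00 = e^ln_cap
    return estimate_t0(rho_X0=1.0, U00=math.exp(-ln_cap), k0=efolds_per_year, gamma0=0.0)


def mean_lifespan(gamma0: float) -> float:
    """Mean protocell lifespan in epochs: ``1 / gamma0``.

    With one epoch per day and the default ``gamma0 = 0.01`` this reads as a
    100-day lifespan.
    """
    if not (gamma0 > 0):
        raise ValueError("gamma0 must be positive")
    return 1.0 / gamma0


def information_capacity_bytes(L: float) -> float:
    """Bytes of inherited information at the top of the zeta axis.

    zeta is the natural log of the bits passed per generation, so the axis
    ceiling corresponds to ``e^L / 8`` bytes (~1e10 at L = 25).
    """
    return math.exp(L) / 8.0


def diffusive_time_factor(eps_ref: float, eps: float) -> float:
    """Run-time multiplier that equalizes diffusive widths across mutation
    scales.

    Diffusive widths grow like ``eps * sqrt(t)``, so a run at mutation scale
    ``eps`` needs ``(eps_ref / eps)^2`` times longer to reach the width of a
    run at ``eps_ref`` — halving eps costs a factor of 4 in time.
    """
    if not (eps_ref > 0 and eps > 0):
        raise ValueError("mutation scales must be positive")
    return (eps_ref / eps) ** 2
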