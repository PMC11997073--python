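"""Convection-diffusion reading of the kernel dynamics.

When mutations are small and the population is much wider than the mutation
kernel, the integrodifferential dynamics reduce to a convection-diffusion
equation (in the rescaled time ``tau = gamma0 t``) with a creation/sink term
``alpha - gamma``, a drift vector ``beta`` and a diffusion tensor ``delta``.
All coefficients are moment integrals of ``ka(source) p(x | source)`` over
the source coordinates, scaled by the dimensionless food factor
``r = (k0 / gamma0) rho_X``.

Away from the domain edges the closed forms hold:

    alpha      ~ r ka
    beta       ~ (r / 2) grad(ka) * eps^2      (drift follows the ka gradient)
    delta_diag ~ (r / 2) ka eps^2,  delta_offdiag ~ 0

so with a nonzero information slope ``a_zeta`` the population is advected
toward higher inherited information, otherwise it merely diffuses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid
from .kernel import SparseKernel, eval_ka
from .params import ModelParams

__all__ = ["DiffusionFields", "full_coefficients", "approx_coefficients", "kernel_second_moments"]


@dataclass(frozen=True)
class DiffusionFields:
    """Per-node convection-diffusion coefficients (flat eta-major order)."""

    r: float                 # (k0 / gamma0) * rho_X
    alpha: np.ndarray        # creation rate
    beta_eta: np.ndarray     # drift, eta component
    beta_zeta: np.ndarray    # drift, zeta component
    delta_ee: np.ndarray     # diffusion tensor entries
    delta_ez: np.ndarray
    delta_zz: np.ndarray
    eps2_eta: float          # nominal second moments eps^2 / 2 of the placement density
    eps2_zeta: float


def full_coefficients(kernel: SparseKernel, rho_X: float, params: ModelParams) -> DiffusionFields:
    """Quadrature evaluation of the six moment integrals at every node.

    Uses the discrete kernel itself: the integral over sources of
    ``(source - x)^k ka(source) p(x | source)`` becomes a sparse row sum of
    the placement matrix.
    """
    if rho_X < 0:
        raise ValueError("rho_X must be nonnegative")
    grid = kernel.grid
    w = grid.cell_weight
    eta = grid.eta_flat
    zeta = grid.zeta_flat
    r = params.k0 / params.gamma0 * rho_X

    # A_ij = m_ij * ka_j * w_j ; density p(i|j) = m_ij / w_i
    A = kernel.P.multiply(kernel.ka * w).tocsr()
    ones = np.asarray(A.sum(axis=1)).ravel()
    m_e = A @ eta
    m_z = A @ zeta
    m_ee = A @ (eta * eta)
    m_zz = A @ (zeta * zeta)
    m_ez = A @ (eta * zeta)

    inv_w = r / w
    alpha = inv_w * ones
    beta_eta = inv_w * (m_e - eta * ones)
    beta_zeta = inv_w * (m_z - zeta * ones)
    delta_ee = inv_w * (m_ee - 2 * eta * m_e + eta * eta * ones)
    delta_zz = inv_w * (m_zz - 2 * zeta * m_z + zeta * zeta * ones)
    delta_ez = inv_w * (m_ez - eta * m_z - zeta * m_e + eta * zeta * ones)

    return DiffusionFields(
        r=r,
        alpha=alpha,
        beta_eta=beta_eta,
        beta_zeta=beta_zeta,
        delta_ee=delta_ee,
        delta_ez=delta_ez,
        delta_zz=delta_zz,
        eps2_eta=params.eps_eta**2 / 2,
        eps2_zeta=params.eps_zeta**2 / 2,
    )


def approx_coefficients(grid: Grid, params: ModelParams, rho_X: float) -> DiffusionFields:
    """Small-mutation closed forms with analytic ``ka`` derivatives.

    ``ka`` is separable, so ``d ka / d eta = b_eta eta k_zeta(x)`` and
    ``d ka / d zeta = c (a_zeta + b_zeta x) k_eta(eta)``.
    """
    if rho_X < 0:
        raise ValueError("rho_X must be nonnegative")
    eta = grid.eta_flat
    zeta = grid.zeta_flat
    r = params.k0 / params.gamma0 * rho_X
    x = params.c * zeta

    k_eta = 1.0 + params.b_eta * eta**2 / 2.0
    k_zeta = 1.0 + params.a_zeta * x + params.b_zeta * x**2 / 2.0
    ka = k_eta * k_zeta
    dka_deta = params.b_eta * eta * k_zeta
    dka_dzeta = params.c * (params.a_zeta + params.b_zeta * x) * k_eta

    e2_eta = params.eps_eta**2
    e2_zeta = params.eps_zeta**2
    zero = np.zeros_like(ka)
    return DiffusionFields(
        r=r,
        alpha=r * ka,
        beta_eta=0.5 * r * dka_deta * e2_eta,
        beta_zeta=0.5 * r * dka_dzeta * e2_zeta,
        delta_ee=0.5 * r * ka * e2_eta,
        delta_ez=zero,
        delta_zz=0.5 * r * ka * e2_zeta,
        eps2_eta=e2_eta / 2,
        eps2_zeta=e2_zeta / 2,
    )


def kernel_second_moments(kernel: SparseKernel, source: int) -> tuple[float, float]:
    """Discrete second moments of the placement mass of one source node.

    For interior sources these reproduce ``eps^2 / 2`` per axis (the
    variance of the untruncated mutation normal).
    """
    grid = kernel.grid
    tgt, mass = kernel.p_masses(source)
    de = grid.eta_flat[tgt] - grid.eta_flat[source]
    dz = grid.zeta_flat[tgt] - grid.zeta_flat[source]
    return float((de * de) @ mass), float((dz * dz) @ mass)
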