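"""Stationary distribution: leading eigenpair of the replication operator.

At stationarity the protocell distribution solves the Fredholm eigenproblem

    integral  ka(s) p(x | s) / gamma(x)  u(s) ds  =  lambda u(x),

with ``lambda = gamma0 / (k0 rho_X)``.  The leading eigenvector is the
stationary shape; the leading eigenvalue fixes the stationary food
concentration ``rho_X* = gamma0 / (k0 lambda)``.  For small mutation scales
``lambda`` approaches the global maximum of the fitness map ``ka / gamma``
and the eigenvector peaks there.

The discrete operator is sparse (the placement matrix keeps only masses
above the threshold z), so the eigenpair is found by power iteration with
L2 renormalization under the grid quadrature weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import SparseKernel

__all__ = ["StationaryResult", "PowerIterationError", "leading_eigenpair"]


class PowerIterationError(RuntimeError):
    """Power iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, result: "StationaryResult"):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class StationaryResult:
    u: np.ndarray          # leading eigenvector, nonnegative, L2-normalized
    lam: float             # leading eigenvalue of ka p / gamma
    lam_tilde: float       # k0 * lam  (the gamma0 / rho_X eigenvalue scaling)
    rho_X_star: float      # implied stationary food concentration
    peak: tuple[float, float]
    iterations: int
    residual: float


def _apply(kernel: SparseKernel, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    # (T v)_i = (1 / gamma_i) sum_j ka_j p(i|j) v_j w_j, with p(i|j) = m_ij / w_i
    return (kernel.P @ (kernel.ka * w * v)) / (kernel.gamma * w)


def leading_eigenpair(
    kernel: SparseKernel,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    v0: np.ndarray | None = None,
) -> StationaryResult:
    """Power iteration for the leading eigenpair.

    Starts from a uniform positive vector (guaranteed overlap with the
    nonnegative leading eigenvector) unless ``v0`` is given; stops when the
    weighted Rayleigh-quotient eigenvalue estimate changes by at most
    ``tol`` between sweeps.
    """
    if not (tol > 0):
        raise ValueError("tol must be positive")
    grid = kernel.grid
    w = grid.cell_weight
    v = np.full(grid.n_nodes, 1.0) if v0 is None else np.asarray(v0, dtype=float).copy()
    if np.any(v < 0) or not np.any(v > 0):
        raise ValueError("initial vector must be nonnegative and nonzero")
    v /= np.sqrt((v * v) @ w)

    lam_prev = np.inf
    lam = 0.0
    residual = np.inf
    for it in range(1, int(max_iter) + 1):
        tv = _apply(kernel, v, w)
        lam = float((v * tv) @ w)
        norm = np.sqrt((tv * tv) @ w)
        if norm == 0:
            raise PowerIterationError(
                "operator annihilated the iterate",
                _result(kernel, v, lam, it, np.inf),
            )
        v = tv / norm
        residual = abs(lam - lam_prev)
        if residual <= tol:
            return _result(kernel, v, lam, it, residual)
        lam_prev = lam
    raise PowerIterationError(
        f"no convergence in {max_iter} iterations (last change {residual:.3e})",
        _result(kernel, v, lam, int(max_iter), residual),
    )


def _result(kernel: SparseKernel, v, lam, iterations, residual) -> StationaryResult:
    grid = kernel.grid
    peak_idx = int(np.argmax(v))
    p = kernel.params
    return StationaryResult(
        u=v,
        lam=lam,
        lam_tilde=p.k0 * lam,
        rho_X_star=p.gamma0 / (p.k0 * lam) if lam > 0 else np.inf,
        peak=(float(grid.eta_flat[peak_idx]), float(grid.zeta_flat[peak_idx])),
        iterations=iterations,
        residual=float(residual),
    )
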