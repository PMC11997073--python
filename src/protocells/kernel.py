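"""Replication kernel on the discrete trait grid.

The replication kernel factorizes as ``K = k0 * ka(source) * p(target |
source)`` where ``ka`` is the total normalized replication rate of a source
phenotype and ``p`` is the mutation placement density of its offspring.
Mutations in the two traits are independent truncated normals, so ``p`` is a
product of two one-dimensional densities with erf edge normalization.

On the grid, each source column of ``p`` is converted to per-node masses
(density times quadrature weight), normalized to 1, sparsified by zeroing
masses below the threshold ``z``, and renormalized — so every column sums to
exactly 1 and the kernel stays column-stochastic.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.special import erf

from .grid import Grid, build_grid
from .params import ModelParams

__all__ = [
    "SparseKernel",
    "FitnessMap",
    "DegenerateKernelError",
    "mutation_density",
    "eval_ka",
    "eval_gamma",
    "build_sparse_kernel",
    "source_mass_profile",
    "fitness_map",
    "fitness_argmax",
    "mirror_eta",
    "save_kernel",
    "load_kernel",
]

_FACT8 = math.factorial(8)


class DegenerateKernelError(RuntimeError):
    """Raised when sparsification removes all offspring mass of some source."""


def _axis_density(t: np.ndarray, src: float, eps: float, lo: float, hi: float) -> np.ndarray:
    """One-dimensional truncated-normal mutation density on ``[lo, hi]``.

    Normalized so that its integral over ``[lo, hi]`` equals 1; the
    normalization uses the erf of the distances from the source to both
    domain edges, which matters for sources within ~6 eps of an edge.
    """
    norm = 0.5 * eps * math.sqrt(math.pi) * (erf((hi - src) / eps) + erf((src - lo) / eps))
    return np.exp(-(((t - src) / eps) ** 2)) / norm


def mutation_density(
    eta, zeta, eta_src: float, zeta_src: float,
    eps_eta: float, eps_zeta: float, L: float,
):
    """Offspring placement density ``p(eta, zeta | eta_src, zeta_src)``.

    Product of two truncated normal densities centered at the parent traits;
    integrates to 1 over ``[-1, 1] x [0, L]`` for any source in the domain.
    """
    if not (eps_eta > 0 and eps_zeta > 0):
        raise ValueError("mutation scales eps_eta, eps_zeta must be positive")
    if not (-1 <= eta_src <= 1 and 0 <= zeta_src <= L):
        raise ValueError(f"source ({eta_src}, {zeta_src}) outside [-1,1]x[0,{L}]")
    return _axis_density(np.asarray(eta, dtype=float), eta_src, eps_eta, -1.0, 1.0) * _axis_density(
        np.asarray(zeta, dtype=float), zeta_src, eps_zeta, 0.0, L
    )


def eval_ka(eta, zeta, params: ModelParams):
    """Total normalized replication rate ``ka(eta, zeta)``.

    Separable form ``(1 + b_eta eta^2 / 2)(1 + a_zeta x + b_zeta x^2 / 2)``
    with ``x = c zeta``; even in eta (L/D symmetry of replication) and equal
    to 1 at the origin.
    """
    eta = np.asarray(eta, dtype=float)
    x = params.c * np.asarray(zeta, dtype=float)
    return (1.0 + params.b_eta * eta**2 / 2.0) * (
        1.0 + params.a_zeta * x + params.b_zeta * x**2 / 2.0
    )


def eval_gamma(eta, zeta, params: ModelParams):
    """Normalized decay rate ``gamma(eta, zeta) = (1 - g eta)(1 + f x^8/8!)``.

    The chiral bias ``g`` lives here (it models differential stability of
    L vs D chemistry); the ``x^8`` factor penalizes very high information
    loads and keeps the fitness peak inside the domain.  ``gamma(0, 0) = 1``.
    """
    if params.g >= 1:
        raise ValueError("asymmetry factor g must be < 1 (gamma would go nonpositive)")
    eta = np.asarray(eta, dtype=float)
    x = params.c * np.asarray(zeta, dtype=float)
    return (1.0 - params.g * eta) * (1.0 + params.f * x**8 / _FACT8)


def _axis_mass_columns(nodes: np.ndarray, weights: np.ndarray, eps: float) -> np.ndarray:
    """Dense ``(targets, sources)`` matrix of normalized 1-D masses.

    Column j holds the discrete offspring mass landing on each target node
    for a parent at node j; every column sums to 1.
    """
    diff = nodes[:, None] - nodes[None, :]
    m = np.exp(-((diff / eps) ** 2)) * weights[:, None]
    return m / m.sum(axis=0)


@dataclass
class SparseKernel:
    """Discretized replication kernel.

    ``P`` is an ``(N, N)`` CSC array with ``P[target, source]`` holding the
    offspring placement mass; every column sums to 1.  ``ka`` and ``gamma``
    are per-node vectors in flat (eta-major) order.

    ``orientation`` marks whether the storage order agrees with the
    canonical eta axis (+1) or is the mirror image (-1); :func:`mirror_eta`
    flips it.  The stochastic stepper consumes randomness in canonical
    order, which makes mirrored simulations exactly mirror-symmetric.
    """

    grid: Grid
    P: sparse.csc_array
    ka: np.ndarray
    gamma: np.ndarray
    k0: float
    params: ModelParams
    orientation: int = 1
    _P_canon: sparse.csc_array | None = field(default=None, repr=False)

    @property
    def nnz_per_source(self) -> np.ndarray:
        return np.diff(self.P.indptr)

    def p_masses(self, source: int) -> tuple[np.ndarray, np.ndarray]:
        """(target indices, masses) of the offspring distribution of a source node."""
        lo, hi = self.P.indptr[source], self.P.indptr[source + 1]
        return self.P.indices[lo:hi], self.P.data[lo:hi]

    @property
    def P_canonical(self) -> sparse.csc_array:
        """The placement matrix with rows/columns in canonical eta order."""
        if self.orientation > 0:
            return self.P
        if self._P_canon is None:
            perm = self.grid.mirror_permutation()
            self._P_canon = sparse.csc_array(self.P[perm][:, perm])
        return self._P_canon


def _column_normalize(P: sparse.csc_array) -> sparse.csc_array:
    colsum = np.asarray(P.sum(axis=0)).ravel()
    if np.any(colsum <= 0):
        bad = int(np.flatnonzero(colsum <= 0)[0])
        raise DegenerateKernelError(
            f"sparsification removed all offspring mass for source node {bad}; "
            "lower the threshold z or refine the grid"
        )
    P.data /= np.repeat(colsum, np.diff(P.indptr))
    return P


def build_sparse_kernel(grid: Grid, params: ModelParams) -> SparseKernel:
    """Build the sparse column-stochastic placement matrix plus the ``ka``
    and ``gamma`` node fields.

    Exploits separability: 1-D mass matrices are built per axis and combined
    with a Kronecker product; the threshold ``z`` is applied to the combined
    per-node mass (1-D masses below ``z`` are dropped early, which is exact
    because the complementary factor never exceeds 1), then columns are
    renormalized to sum to 1.
    """
    if abs(grid.L - params.L) > 1e-12 * max(1.0, params.L):
        raise ValueError(f"grid L={grid.L} does not match params L={params.L}")
    z = params.z
    if z >= 1:
        raise DegenerateKernelError("threshold z >= 1 removes every offspring mass")

    m_eta = _axis_mass_columns(grid.eta_nodes, grid.eta_weights, params.eps_eta)
    m_zeta = _axis_mass_columns(grid.zeta_nodes, grid.zeta_weights, params.eps_zeta)
    # safe pre-thinning: a product mass >= z needs both factors >= z
    m_eta[m_eta < z] = 0.0
    m_zeta[m_zeta < z] = 0.0

    P = sparse.kron(sparse.csc_array(m_eta), sparse.csc_array(m_zeta), format="csc")
    P.data[P.data < z] = 0.0
    P.eliminate_zeros()
    P = _column_normalize(sparse.csc_array(P))

    ka = np.asarray(eval_ka(grid.eta_flat, grid.zeta_flat, params))
    gamma = np.asarray(eval_gamma(grid.eta_flat, grid.zeta_flat, params))
    return SparseKernel(grid=grid, P=P, ka=ka, gamma=gamma, k0=params.k0, params=params)


def source_mass_profile(
    grid: Grid, params: ModelParams, eta_src: float, zeta_src: float
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholded offspring masses of a single source without building the
    full kernel.

    The source snaps to the nearest grid node.  Returns ``(flat target
    indices, masses)`` with masses summing to 1; useful for sparsity
    diagnostics on large grids.
    """
    i_eta = int(np.argmin(np.abs(grid.eta_nodes - eta_src)))
    i_zeta = int(np.argmin(np.abs(grid.zeta_nodes - zeta_src)))
    col_eta = _axis_mass_columns(grid.eta_nodes, grid.eta_weights, params.eps_eta)[:, i_eta]
    col_zeta = _axis_mass_columns(grid.zeta_nodes, grid.zeta_weights, params.eps_zeta)[:, i_zeta]
    masses = np.outer(col_eta, col_zeta).ravel()
    masses[masses < params.z] = 0.0
    keep = np.flatnonzero(masses)
    if keep.size == 0:
        raise DegenerateKernelError("threshold z removed all masses for this source")
    return keep, masses[keep] / masses[keep].sum()


@dataclass(frozen=True)
class FitnessMap:
    """Per-node fitness ``f = ka / gamma`` with its global maxima.

    ``lambda_est`` (the maximum value) estimates the leading eigenvalue of
    the stationary replication operator; the argmax locates the stationary
    peak.  With ``g > 0`` the maximum is unique; with ``g = 0`` the eta
    evenness of both ``ka`` and ``gamma`` makes maxima come in mirrored
    pairs.
    """

    values: np.ndarray
    argmax_idx: tuple[int, ...]
    argmax_nodes: tuple[tuple[float, float], ...]
    lambda_est: float


def fitness_map(kernel: SparseKernel) -> FitnessMap:
    values = kernel.ka / kernel.gamma
    best = float(values.max())
    idx = tuple(int(i) for i in np.flatnonzero(values == best))
    grid = kernel.grid
    nodes = tuple((float(grid.eta_flat[i]), float(grid.zeta_flat[i])) for i in idx)
    return FitnessMap(values=values, argmax_idx=idx, argmax_nodes=nodes, lambda_est=best)


def fitness_argmax(params: ModelParams, xatol: float = 1e-10) -> tuple[float, float, float]:
    """Continuous maximizer of ``ka / gamma`` over the domain.

    Both factors are separable, so the two axes are optimized independently
    (bounded golden-section refinement plus the endpoints).  Returns
    ``(eta0, zeta0, max value)``.
    """
    from scipy.optimize import minimize_scalar

    def best_1d(fun, lo, hi):
        res = minimize_scalar(lambda v: -fun(v), bounds=(lo, hi), method="bounded",
                              options={"xatol": xatol})
        cands = [lo, hi, float(res.x)]
        vals = [fun(v) for v in cands]
        i = int(np.argmax(vals))
        return cands[i], vals[i]

    eta0, f_eta = best_1d(
        lambda e: float(eval_ka(e, 0.0, params) / eval_gamma(e, 0.0, params)), -1.0, 1.0
    )
    zeta0, f_zeta = best_1d(
        lambda zt: float(eval_ka(0.0, zt, params) / eval_gamma(0.0, zt, params)), 0.0, params.L
    )
    # separable product: f(eta, zeta) = f_eta(eta) * f_zeta(zeta) / f(0,0) scaling
    value = float(
        eval_ka(eta0, zeta0, params) / eval_gamma(eta0, zeta0, params)
    )
    return eta0, zeta0, value


def mirror_eta(kernel: SparseKernel) -> SparseKernel:
    """Relabel the kernel under ``eta -> -eta``.

    Physically this is the mirror-image model; for ``g = 0`` the node fields
    are unchanged and only the storage orientation flips.  The mirrored
    kernel remembers the original storage order, so stochastic runs driven
    by it consume randomness in mirrored node order and reproduce the
    mirrored trajectory exactly.
    """
    perm = kernel.grid.mirror_permutation()
    P_m = sparse.csc_array(kernel.P[perm][:, perm])
    return SparseKernel(
        grid=kernel.grid,
        P=P_m,
        ka=kernel.ka[perm],
        gamma=kernel.gamma[perm],
        k0=kernel.k0,
        params=kernel.params,
        orientation=-kernel.orientation,
        _P_canon=kernel.P if kernel.orientation > 0 else None,
    )


def save_kernel(kernel: SparseKernel, path) -> None:
    """Serialize a kernel (triplets + node fields + parameters) to ``.npz``."""
    coo = kernel.P.tocoo()
    np.savez_compressed(
        path,
        target=coo.row.astype(np.int64),
        source=coo.col.astype(np.int64),
        mass=coo.data,
        ka=kernel.ka,
        gamma=kernel.gamma,
        orientation=np.int64(kernel.orientation),
        params_json=np.bytes_(json.dumps(kernel.params.to_dict()).encode()),
        d=np.int64(kernel.grid.d),
    )


def load_kernel(path) -> SparseKernel:
    with np.load(path) as npz:
        pd = json.loads(bytes(npz["params_json"]).decode())
        params = ModelParams(**pd)
        d = int(npz["d"])
        grid = build_grid(d, params.L)
        n = grid.n_nodes
        P = sparse.csc_array(
            sparse.coo_array((npz["mass"], (npz["target"], npz["source"])), shape=(n, n))
        )
        return SparseKernel(
            grid=grid,
            P=P,
            ka=npz["ka"],
            gamma=npz["gamma"],
            k0=params.k0,
            params=params,
            orientation=int(npz["orientation"]),
        )
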