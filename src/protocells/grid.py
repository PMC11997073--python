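"""Discretization of the two-dimensional trait space.

The model lives on the rectangle ``[-1, 1] x [0, L]``.  The first axis is the
enantiomeric excess ``eta`` (-1 = pure D, +1 = pure L, 0 = racemic), the
second is the inherited information ``zeta`` (interpreted as the natural log
of bits passed per generation).  The grid is node-centered and includes the
domain endpoints, so the homochiral states ``eta = +-1`` are representable.

Flat node ordering is eta-major: ``flat = i_eta * d + i_zeta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "build_grid"]


@dataclass(frozen=True)
class Grid:
    """Uniform node-centered grid on ``[-1, 1] x [0, L]`` with trapezoidal
    quadrature weights.

    ``eta_nodes`` is built symmetrically so that ``eta_nodes[i] ==
    -eta_nodes[d - 1 - i]`` holds bitwise; several evenness invariants of the
    model rely on that.
    """

    d: int
    L: float
    eta_nodes: np.ndarray
    zeta_nodes: np.ndarray
    d_eta: float
    d_zeta: float
    eta_weights: np.ndarray
    zeta_weights: np.ndarray
    # flat (eta-major) views, precomputed once
    eta_flat: np.ndarray = field(repr=False, default=None)
    zeta_flat: np.ndarray = field(repr=False, default=None)
    cell_weight: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.d * self.d

    def flat_index(self, i_eta: int, i_zeta: int) -> int:
        return int(i_eta) * self.d + int(i_zeta)

    def unravel(self, flat: int) -> tuple[int, int]:
        return divmod(int(flat), self.d)

    def nearest_node(self, eta: float, zeta: float) -> int:
        """Flat index of the grid node closest to ``(eta, zeta)``.

        Ties resolve to the lower index (argmin convention).
        """
        i_eta = int(np.argmin(np.abs(self.eta_nodes - eta)))
        i_zeta = int(np.argmin(np.abs(self.zeta_nodes - zeta)))
        return self.flat_index(i_eta, i_zeta)

    def mirror_permutation(self) -> np.ndarray:
        """Flat-index permutation implementing ``eta -> -eta``."""
        i_eta, i_zeta = np.divmod(np.arange(self.n_nodes), self.d)
        return (self.d - 1 - i_eta) * self.d + i_zeta


def build_grid(d: int, L: float) -> Grid:
    """Build a ``d x d`` node-centered grid on ``[-1, 1] x [0, L]``.

    Quadrature weights are trapezoidal: interior nodes carry
    ``d_eta * d_zeta``, edges half and corners a quarter of that, so that
    ``sum(cell_weight) == 2 L`` (the domain area) to rounding error.
    """
    if isinstance(d, bool) or not isinstance(d, (int, np.integer)):
        raise ValueError(f"grid size d must be an integer, got {d!r}")
    if d < 2:
        raise ValueError(f"grid size d must be >= 2, got {d}")
    if not (L > 0):
        raise ValueError(f"upper zeta bound L must be positive, got {L}")

    i = np.arange(d)
    # symmetric construction: eta[i] == -eta[d-1-i] exactly in floating point
    eta = (2.0 * i - (d - 1)) / (d - 1)
    zeta = np.linspace(0.0, float(L), d)
    d_eta = 2.0 / (d - 1)
    d_zeta = float(L) / (d - 1)

    w_eta = np.full(d, d_eta)
    w_eta[[0, -1]] *= 0.5
    w_zeta = np.full(d, d_zeta)
    w_zeta[[0, -1]] *= 0.5

    eta_flat = np.repeat(eta, d)
    zeta_flat = np.tile(zeta, d)
    cell_weight = np.outer(w_eta, w_zeta).ravel()

    return Grid(
        d=int(d),
        L=float(L),
        eta_nodes=eta,
        zeta_nodes=zeta,
        d_eta=d_eta,
        d_zeta=d_zeta,
        eta_weights=w_eta,
        zeta_weights=w_zeta,
        eta_flat=eta_flat,
        zeta_flat=zeta_flat,
        cell_weight=cell_weight,
    )
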