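"""Summary statistics, evolutionary-stage segmentation, species detection.

The distribution summaries are the total protocell amount, the means and
standard deviations of the normalized distribution along both traits, and
the food/waste fractions of the total matter (reported in percent, matching
the usual presentation of the food-depletion curves).

The four stages of a run — exponential growth, diffusive spreading,
stochastic runaway, relaxation to the stationary peak — show up as drops
and plateaus of the food fraction; :func:`detect_stages` segments that
curve heuristically.  :func:`detect_species` finds non-connected groups of
the distribution ("species") as connected components above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid

__all__ = ["SummaryStats", "Trajectory", "Species", "summarize", "detect_stages", "detect_species"]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class SummaryStats:
    """Moments of the protocell distribution plus matter bookkeeping.

    When the population is empty the moments are undefined and reported as
    ``None`` (never as zero, which would fake a racemic reading).
    """

    t: float
    U0: float
    mu_eta: float | None
    sigma_eta: float | None
    mu_zeta: float | None
    sigma_zeta: float | None
    food_frac: float     # percent of total matter
    waste_frac: float    # percent of total matter

    @property
    def defined(self) -> bool:
        return self.mu_eta is not None


@dataclass
class Trajectory:
    series: list
    snapshots: list
    stage_bounds: list
    manifest: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": [s.t for s in self.series],
                "U0": [s.U0 for s in self.series],
                "mu_eta": [s.mu_eta for s in self.series],
                "sigma_eta": [s.sigma_eta for s in self.series],
                "mu_zeta": [s.mu_zeta for s in self.series],
                "sigma_zeta": [s.sigma_zeta for s in self.series],
                "food_pct": [s.food_frac for s in self.series],
                "waste_pct": [s.waste_frac for s in self.series],
            }
        )


def summarize(
    field_values: np.ndarray,
    grid: Grid,
    rho_X: float,
    rho_W: float,
    t: float = 0.0,
    weighted: bool | None = None,
) -> SummaryStats:
    """Weighted moments of the distribution plus food/waste fractions.

    ``weighted=None`` infers the mode from the dtype: float fields are
    concentrations integrated with the grid quadrature weights, integer
    fields are plain counts.
    """
    v = np.asarray(field_values)
    if v.shape != (grid.n_nodes,):
        raise ValueError("field size does not match the grid")
    if np.any(v < 0):
        raise ValueError("field must be nonnegative")
    if weighted is None:
        weighted = np.issubdtype(v.dtype, np.floating)
    mass = v * grid.cell_weight if weighted else v.astype(float)

    U0 = float(mass.sum())
    total = rho_X + rho_W + U0
    food = 100.0 * rho_X / total if total > 0 else 0.0
    waste = 100.0 * rho_W / total if total > 0 else 0.0
    if U0 == 0:
        return SummaryStats(t=t, U0=0.0, mu_eta=None, sigma_eta=None,
                            mu_zeta=None, sigma_zeta=None, food_frac=food, waste_frac=waste)

    u = mass / U0
    mu_e = float(grid.eta_flat @ u)
    mu_z = float(grid.zeta_flat @ u)
    var_e = float(((grid.eta_flat - mu_e) ** 2) @ u)
    var_z = float(((grid.zeta_flat - mu_z) ** 2) @ u)
    return SummaryStats(
        t=t,
        U0=U0,
        mu_eta=mu_e,
        sigma_eta=float(np.sqrt(max(var_e, 0.0))),
        mu_zeta=mu_z,
        sigma_zeta=float(np.sqrt(max(var_z, 0.0))),
        food_frac=food,
        waste_frac=waste,
    )


def detect_stages(
    food_series,
    drop_frac: float = 0.05,
    min_run: int = 3,
    smooth: int = 5,
) -> list[int]:
    """Segment a food-fraction series into evolutionary stages.

    A step is "dropping" when the smoothed per-step food decrease exceeds
    ``drop_frac`` times the largest observed decrease.  Sustained dropping
    runs (length >= ``min_run``) delimit the stages: the end of the first
    run closes stage 1, the onset of each later run opens the next
    transition, and the end of the last run starts the final relaxation.
    Returns the sorted unique boundary steps (empty for a flat series).
    """
    food = np.asarray(food_series, dtype=float)
    if food.size < 10:
        raise ValueError("food series too short to segment (need >= 10 points)")
    drops = -np.diff(food)
    if smooth > 1:
        pad = smooth // 2
        padded = np.pad(drops, pad, mode="edge")
        drops = np.convolve(padded, np.ones(smooth) / smooth, mode="valid")[: drops.size]
    peak = drops.max(initial=0.0)
    if peak <= 0:
        return []
    mask = drops > drop_frac * peak

    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    if start is not None and mask.size - start >= min_run:
        runs.append((start, mask.size))
    if not runs:
        return []

    bounds = {runs[0][1]}
    for s, _ in runs[1:]:
        bounds.add(s)
    bounds.add(runs[-1][1])
    return sorted(int(b) for b in bounds if b <= food.size - 1)


@dataclass(frozen=True)
class Species:
    """One connected component of the above-threshold distribution."""

    mass: float
    centroid: tuple[float, float]            # (eta, zeta)
    bbox: tuple[float, float, float, float]  # eta_min, eta_max, zeta_min, zeta_max
    n_nodes: int


def detect_species(
    field_values: np.ndarray,
    grid: Grid,
    threshold_frac: float = 1e-3,
    weighted: bool | None = None,
) -> list[Species]:
    """Connected components (4-neighbor) of nodes above
    ``threshold_frac * max(field)``.

    The default threshold separates genuinely split bumps while ignoring
    the faint mutation halo around each.  Components are returned largest
    mass first.
    """
    v = np.asarray(field_values)
    if v.shape != (grid.n_nodes,):
        raise ValueError("field size does not match the grid")
    vmax = v.max(initial=0)
    if vmax <= 0:
        return []
    if weighted is None:
        weighted = np.issubdtype(v.dtype, np.floating)
    mass = (v * grid.cell_weight if weighted else v.astype(float)).reshape(grid.d, grid.d)

    labels, n_comp = ndimage.label((v > threshold_frac * vmax).reshape(grid.d, grid.d),
                                   structure=_FOUR_CONN)
    out = []
    for lab in range(1, n_comp + 1):
        sel = labels == lab
        m = mass[sel].sum()
        i_eta, i_zeta = np.nonzero(sel)
        weights = mass[sel]
        if m > 0:
            c_eta = float(grid.eta_nodes[i_eta] @ weights / m)
            c_zeta = float(grid.zeta_nodes[i_zeta] @ weights / m)
        else:  # all-zero component mass (can happen only at threshold 0)
            c_eta = float(grid.eta_nodes[i_eta].mean())
            c_zeta = float(grid.zeta_nodes[i_zeta].mean())
        out.append(
            Species(
                mass=float(m),
                centroid=(c_eta, c_zeta),
                bbox=(
                    float(grid.eta_nodes[i_eta.min()]),
                    float(grid.eta_nodes[i_eta.max()]),
                    float(grid.zeta_nodes[i_zeta.min()]),
                    float(grid.zeta_nodes[i_zeta.max()]),
                ),
                n_nodes=int(sel.sum()),
            )
        )
    out.sort(key=lambda sp: (-sp.mass, sp.bbox))
    return out
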