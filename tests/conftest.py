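"""Shared fixtures.

The stochastic ensembles are session-scoped because several tests (module
tests and the acceptance suite) interrogate different aspects of the same
scaled-down simulation campaigns.  All randomness is seeded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import protocells as pc


@pytest.fixture(scope="session")
def tiny():
    """20x20 grid with a coarse but resolvable kernel (the standard small
    test system)."""
    return pc.make_fixture("tiny-grid")


@pytest.fixture(scope="session")
def table_params():
    """Reference parameterization, larger mutation-scale variant."""
    return pc.ModelParams(eps_eta=0.01, eps_zeta=0.01)


@pytest.fixture(scope="session")
def kernel50(table_params):
    """d=50 kernel at the reference parameters (stationary-analysis grid)."""
    grid = pc.build_grid(50, table_params.L)
    return pc.build_sparse_kernel(grid, table_params)


@pytest.fixture(scope="session")
def fine_kernel():
    """Finely resolved kernel (d=201, L=2, eps=0.01) for the
    convection-diffusion moment checks; spacing equals eps on both axes."""
    params = pc.ModelParams(eps_eta=0.01, eps_zeta=0.01, L=2.0)
    grid = pc.build_grid(201, 2.0)
    return pc.build_sparse_kernel(grid, params), params


@pytest.fixture(scope="session")
def euler_limit():
    """Mean tau-leaping trajectory vs the Euler trajectory at large rho0.

    rho0 = 1e12 with the initial population scaled to the same concentration
    (U00/rho0 = 1e-3) on a 20x20 grid, 100 steps, 20 seeds.
    """
    params = pc.ModelParams(eps_eta=0.3, eps_zeta=1.5, rho0=10**12, U00=10**9)
    grid = pc.build_grid(20, params.L)
    kernel = pc.build_sparse_kernel(grid, params)

    state = pc.init_real_state(grid, params)
    euler = []
    for _ in range(100):
        state = pc.step_euler(state, kernel, params)
        euler.append(state.U @ grid.cell_weight)

    trajs = []
    for s in range(20):
        st = pc.init_state(grid, params, seed=100 + s)
        tr = []
        for _ in range(100):
            st = pc.step_tau(st, kernel, params)
            tr.append(st.N_U.sum() / params.rho0)
        trajs.append(tr)
    return np.asarray(euler), np.asarray(trajs).mean(axis=0)


def _symbreak_params(g, rho0):
    # fast eta-only scenario: no information structure (b_zeta = f = 0,
    # zeta mutations below grid resolution), strong replication advantage
    # of homochiral states, short protocell lifespan for quick turnover
    return pc.ModelParams(
        k0=1.0, gamma0=0.25, s=1.0, b_eta=1.0, a_zeta=0.0, b_zeta=0.0,
        f=0.0, g=g, eps_eta=0.15, eps_zeta=0.01, rho0=rho0, U00=1000,
    )


def _final_mu_eta(d, params, seeds, T=1500):
    grid = pc.build_grid(d, params.L)
    kernel = pc.build_sparse_kernel(grid, params)
    out = []
    for s in seeds:
        st = pc.init_state(grid, params, seed=s)
        for _ in range(T):
            st = pc.step_tau(st, kernel, params)
        out.append(pc.summarize(st.N_U, grid, st.N_X, st.N_W).mu_eta)
    return out


@pytest.fixture(scope="session")
def symbreak_mu():
    """Final mu_eta of 10 seeds with a grid-resolvable chiral bias
    (d=100, g=0.02, rho0=1e9)."""
    return _final_mu_eta(100, _symbreak_params(0.02, 10**9), range(10))


@pytest.fixture(scope="session")
def randomsign_mu():
    """Final mu_eta of 10 seeds without bias (g=0) at small rho0 on a
    centered grid."""
    return _final_mu_eta(101, _symbreak_params(0.0, 10**6), range(10))


@pytest.fixture(scope="session")
def width_scaling():
    """Diffusive width campaign in a drift-free neutral configuration.

    Returns the ensemble-mean sigma_eta series of the eps=0.04 runs, and the
    widths entering the 4x time-rescaling comparison: sigma(eps, T) vs
    sigma(eps/2, 4T).
    """
    def base(eps):
        return pc.ModelParams(
            k0=1.0, gamma0=0.1, b_eta=0.0, a_zeta=0.0, b_zeta=0.0, f=0.0, g=0.0,
            eps_eta=eps, eps_zeta=0.01, rho0=10**8, U00=1000,
        )

    def run(params, T, seed, record):
        grid = pc.build_grid(101, params.L)
        kernel = pc.build_sparse_kernel(grid, params)
        st = pc.init_state(grid, params, seed=seed)
        out = {}
        for i in range(1, T + 1):
            st = pc.step_tau(st, kernel, params)
            if i in record:
                out[i] = pc.summarize(st.N_U, grid, st.N_X, st.N_W).sigma_eta
        return out

    record_coarse = set(range(500, 2001, 100))
    coarse = [run(base(0.04), 2000, 10 + s, record_coarse) for s in range(10)]
    fine = [run(base(0.02), 8000, 30 + s, {8000}) for s in range(5)]

    ts = sorted(record_coarse)
    sigma_coarse = {t: float(np.mean([r[t] for r in coarse])) for t in ts}
    sigma_fine_4T = float(np.mean([r[8000] for r in fine]))
    return {
        "times": ts,
        "sigma_coarse": sigma_coarse,
        "sigma_at_T": sigma_coarse[2000],
        "sigma_half_eps_at_4T": sigma_fine_4T,
    }


@pytest.fixture(scope="session")
def long_conservation(tiny):
    """10^4 tau-leaping steps on the tiny system; step_tau verifies the
    molecule count internally, the fixture returns the final state."""
    grid, kernel, params = tiny
    st = pc.init_state(grid, params, seed=3)
    for _ in range(10_000):
        st = pc.step_tau(st, kernel, params)
    return st, params
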