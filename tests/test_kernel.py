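import math

import numpy as np
import pytest

import protocells as pc


def _fine_integral(eta_src, zeta_src, eps, L):
    """Trapezoidal integral of the mutation density over the full domain."""
    eta = np.linspace(-1, 1, 4001)
    zeta = np.linspace(0, L, 4001)
    dens = pc.mutation_density(
        eta[:, None], zeta[None, :], eta_src, zeta_src, eps, eps, L
    )
    return np.trapezoid(np.trapezoid(dens, zeta, axis=1), eta)


class TestMutationDensity:
    @pytest.mark.parametrize("src", [(0.0, 12.5), (0.9, 1.0), (-1.0, 0.0), (1.0, 25.0)])
    def test_integrates_to_one_everywhere(self, src):
        # edge and corner sources rely on the erf normalization
        assert _fine_integral(*src, eps=0.05, L=25.0) == pytest.approx(1.0, abs=1e-6)

    def test_interior_peak_value(self):
        val = pc.mutation_density(0.0, 12.5, 0.0, 12.5, 0.01, 0.01, 25.0)
        assert val == pytest.approx(1 / (0.01 * 0.01 * math.pi), rel=1e-6)
        assert float(val) == pytest.approx(3183.1, rel=1e-4)

    def test_symmetric_about_interior_source(self):
        a = 0.02
        left = pc.mutation_density(-a, 12.5, 0.0, 12.5, 0.01, 0.01, 25.0)
        right = pc.mutation_density(a, 12.5, 0.0, 12.5, 0.01, 0.01, 25.0)
        assert left == pytest.approx(right, rel=1e-14)

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            pc.mutation_density(0, 1, 0, 1, -0.01, 0.01, 25.0)
        with pytest.raises(ValueError):
            pc.mutation_density(0, 1, 2.0, 1, 0.01, 0.01, 25.0)


class TestRateFields:
    def test_ka_reference_values(self):
        p = pc.ModelParams()
        assert pc.eval_ka(0, 0, p) == 1.0
        assert pc.eval_ka(1, 0, p) == 1.5
        p2 = pc.ModelParams(a_zeta=1.0, b_zeta=1.0)
        assert pc.eval_ka(0, 25, p2) == pytest.approx(3.625)

    def test_gamma_reference_values(self):
        p = pc.ModelParams()
        assert pc.eval_gamma(0, 0, p) == 1.0
        assert pc.eval_gamma(1, 0, p) == pytest.approx(0.998)
        assert pc.eval_gamma(0, 25, p) == pytest.approx(1.63564, abs=1e-5)

    def test_ka_even_in_eta_bitwise(self):
        g = pc.build_grid(40, 25.0)
        p = pc.ModelParams()
        ka = np.asarray(pc.eval_ka(g.eta_flat, g.zeta_flat, p))
        assert np.array_equal(ka, ka[g.mirror_permutation()])

    def test_gamma_origin_normalization_on_grid(self, tiny):
        grid, kernel, params = tiny
        # zeta = 0 row exists on every grid; check the closed form there
        i = grid.nearest_node(grid.eta_nodes[3], 0.0)
        eta = grid.eta_flat[i]
        assert kernel.gamma[i] == pytest.approx(1 - params.g * eta, rel=1e-14)


class TestSparseKernel:
    def test_columns_sum_to_one(self, tiny):
        _, kernel, _ = tiny
        colsums = np.asarray(kernel.P.sum(axis=0)).ravel()
        assert np.abs(colsums - 1).max() < 1e-12
        assert (kernel.P.data > 0).all()

    def test_thresholding_can_degenerate(self):
        grid = pc.build_grid(20, 25.0)
        params = pc.ModelParams(eps_eta=0.2, eps_zeta=1.5, z=0.999)
        with pytest.raises(pc.DegenerateKernelError):
            pc.build_sparse_kernel(grid, params)

    def test_threshold_at_or_above_one_invalid(self):
        with pytest.raises(ValueError):
            pc.ModelParams(z=1.0)

    def test_monotone_sparsity_in_z(self):
        grid = pc.build_grid(30, 25.0)
        nnz = []
        for z in (1e-8, 1e-5, 1e-2):
            params = pc.ModelParams(eps_eta=0.2, eps_zeta=1.5, z=z)
            nnz.append(pc.build_sparse_kernel(grid, params).nnz_per_source)
        assert (nnz[0] >= nnz[1]).all() and (nnz[1] >= nnz[2]).all()

    def test_interior_mean_matches_source(self, fine_kernel):
        kernel, params = fine_kernel
        grid = kernel.grid
        src = grid.nearest_node(0.2, 1.0)  # deeper than 6 eps from every edge
        tgt, mass = kernel.p_masses(src)
        mean_eta = grid.eta_flat[tgt] @ mass
        mean_zeta = grid.zeta_flat[tgt] @ mass
        assert abs(mean_eta - grid.eta_flat[src]) < 1e-6
        assert abs(mean_zeta - grid.zeta_flat[src]) < 1e-6

    def test_full_size_interior_sparsity(self):
        # d=500 grid, eps=0.01, z=1e-5: between 10 and 100 surviving targets
        grid = pc.build_grid(500, 25.0)
        params = pc.ModelParams(eps_eta=0.01, eps_zeta=0.01)
        idx, masses = pc.source_mass_profile(grid, params, 0.0, 12.5)
        assert 10 <= idx.size <= 100
        assert masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_save_load_roundtrip(self, tiny, tmp_path):
        _, kernel, _ = tiny
        path = tmp_path / "kernel.npz"
        pc.save_kernel(kernel, path)
        back = pc.load_kernel(path)
        assert np.allclose((kernel.P - back.P).toarray() if hasattr(kernel.P, "toarray") else 0, 0)
        assert np.array_equal(kernel.ka, back.ka)
        assert np.array_equal(kernel.gamma, back.gamma)
        assert back.grid.d == kernel.grid.d


class TestFitnessMap:
    def test_reference_peak_location(self, kernel50):
        fm = pc.fitness_map(kernel50)
        assert len(fm.argmax_nodes) == 1
        eta0, zeta0 = fm.argmax_nodes[0]
        assert eta0 == 1.0
        assert 20.0 <= zeta0 <= 21.0
        assert fm.lambda_est == fm.values.max()

    def test_mirrored_pair_without_bias(self):
        grid = pc.build_grid(21, 25.0)
        params = pc.ModelParams(g=0.0, eps_eta=0.2, eps_zeta=1.5)
        fm = pc.fitness_map(pc.build_sparse_kernel(grid, params))
        assert len(fm.argmax_nodes) == 2
        (e1, z1), (e2, z2) = fm.argmax_nodes
        assert e1 == -e2 and z1 == z2

    def test_no_limit_factor_pushes_to_boundary(self):
        grid = pc.build_grid(26, 25.0)
        params = pc.ModelParams(f=0.0, a_zeta=1.0, eps_eta=0.2, eps_zeta=1.5)
        fm = pc.fitness_map(pc.build_sparse_kernel(grid, params))
        assert all(z == 25.0 for _, z in fm.argmax_nodes)

    def test_continuous_argmax_agrees_with_grid(self, kernel50):
        params = kernel50.params
        eta0, zeta0, value = pc.fitness_argmax(params)
        fm = pc.fitness_map(kernel50)
        assert eta0 == fm.argmax_nodes[0][0]
        assert abs(zeta0 - fm.argmax_nodes[0][1]) <= kernel50.grid.d_zeta
        assert value >= fm.lambda_est
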