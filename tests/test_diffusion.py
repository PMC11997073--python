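import numpy as np
import pytest

import protocells as pc

RHO_X = 0.1


def _interior(grid, params, depth=6.0):
    e, z = grid.eta_flat, grid.zeta_flat
    return (
        (np.abs(e) < 1 - depth * params.eps_eta)
        & (z > depth * params.eps_zeta)
        & (z < grid.L - depth * params.eps_zeta)
    )


class TestFullCoefficients:
    def test_drift_vanishes_on_symmetry_axis(self, fine_kernel):
        kernel, params = fine_kernel
        fields = pc.full_coefficients(kernel, RHO_X, params)
        grid = kernel.grid
        on_axis = (grid.eta_flat == 0.0) & _interior(grid, params)
        assert on_axis.any()
        assert np.abs(fields.beta_eta[on_axis]).max() < 1e-8

    def test_alpha_matches_r_ka_interior(self, fine_kernel):
        kernel, params = fine_kernel
        fields = pc.full_coefficients(kernel, RHO_X, params)
        interior = _interior(kernel.grid, params)
        r_ka = fields.r * kernel.ka
        rel = np.abs(fields.alpha - r_ka) / r_ka
        assert rel[interior].max() < 1e-3

    def test_diagonal_diffusion_matches_closed_form(self, fine_kernel):
        kernel, params = fine_kernel
        fields = pc.full_coefficients(kernel, RHO_X, params)
        interior = _interior(kernel.grid, params)
        expected = 0.5 * fields.r * kernel.ka * params.eps_eta**2
        rel = np.abs(fields.delta_ee - expected) / expected
        assert rel[interior].max() < 0.01

    def test_cross_diffusion_negligible(self, fine_kernel):
        # the exact cross moment is O(eps^4), of the order beta_eta*beta_zeta/r:
        # three orders below the diagonal entries at eps = 0.01, and exactly
        # zero on the eta symmetry axis
        kernel, params = fine_kernel
        fields = pc.full_coefficients(kernel, RHO_X, params)
        grid = kernel.grid
        interior = _interior(grid, params)
        assert (np.abs(fields.delta_ez[interior]) <= 1e-3 * fields.delta_ee[interior]).all()
        on_axis = (grid.eta_flat == 0.0) & interior
        assert np.abs(fields.delta_ez[on_axis]).max() < 1e-10 * fields.delta_ee[on_axis].max()

    def test_positive_creation_rate(self, fine_kernel):
        kernel, params = fine_kernel
        fields = pc.full_coefficients(kernel, RHO_X, params)
        assert (fields.alpha > 0).all()

    def test_invalid_rho_X(self, fine_kernel):
        kernel, params = fine_kernel
        with pytest.raises(ValueError):
            pc.full_coefficients(kernel, -1.0, params)


class TestApproxCoefficients:
    def test_information_drift_at_origin(self):
        params = pc.ModelParams(a_zeta=1.0, eps_eta=0.01, eps_zeta=0.01)
        grid = pc.build_grid(51, params.L)
        fields = pc.approx_coefficients(grid, params, RHO_X)
        origin = grid.nearest_node(0.0, 0.0)
        expected = 0.5 * fields.r * params.a_zeta * params.c * params.eps_zeta**2
        assert fields.beta_zeta[origin] == pytest.approx(expected, rel=1e-12)
        assert fields.beta_eta[origin] == 0.0

    def test_no_drift_without_information_slope(self):
        params = pc.ModelParams(a_zeta=0.0, eps_eta=0.01, eps_zeta=0.01)
        grid = pc.build_grid(51, params.L)
        fields = pc.approx_coefficients(grid, params, RHO_X)
        origin = grid.nearest_node(0.0, 0.0)
        assert fields.beta_zeta[origin] == 0.0

    def test_drift_parallels_ka_gradient(self):
        params = pc.ModelParams(a_zeta=1.0, eps_eta=0.02, eps_zeta=0.02)
        grid = pc.build_grid(51, params.L)
        fields = pc.approx_coefficients(grid, params, RHO_X)
        h = 1e-6
        for eta, zeta in [(0.4, 10.0), (-0.6, 5.0), (0.2, 20.0)]:
            g_eta = (pc.eval_ka(eta + h, zeta, params) - pc.eval_ka(eta - h, zeta, params)) / (2 * h)
            g_zeta = (pc.eval_ka(eta, zeta + h, params) - pc.eval_ka(eta, zeta - h, params)) / (2 * h)
            i = grid.nearest_node(eta, zeta)
            # equal eps on both axes: beta is proportional to grad ka
            ratio_expected = g_eta / g_zeta
            ratio = fields.beta_eta[i] / fields.beta_zeta[i]
            assert ratio == pytest.approx(ratio_expected, rel=1e-2)


class TestFullVsApprox:
    def test_interior_agreement_within_5_percent(self, fine_kernel):
        kernel, params = fine_kernel
        grid = kernel.grid
        full = pc.full_coefficients(kernel, RHO_X, params)
        approx = pc.approx_coefficients(grid, params, RHO_X)
        interior = _interior(grid, params)

        for name in ("alpha", "delta_ee", "delta_zz"):
            f, a = getattr(full, name)[interior], getattr(approx, name)[interior]
            assert (np.abs(f - a) / np.abs(a)).max() < 0.05
        for name in ("beta_eta", "beta_zeta"):
            f, a = getattr(full, name)[interior], getattr(approx, name)[interior]
            scale = np.abs(a).max()
            big = np.abs(a) > 1e-2 * scale
            assert (np.abs(f[big] - a[big]) / np.abs(a[big])).max(initial=0) < 0.05
            assert np.abs(f[~big] - a[~big]).max(initial=0) < 0.05 * scale

    def test_discrepancy_shrinks_with_eps(self):
        # on a grid that resolves both scales, the closed-form error
        # (Taylor O(eps^2) plus threshold truncation) grows with eps
        def max_rel(eps):
            params = pc.ModelParams(eps_eta=eps, eps_zeta=eps, L=2.0)
            grid = pc.build_grid(201, 2.0)
            kernel = pc.build_sparse_kernel(grid, params)
            full = pc.full_coefficients(kernel, RHO_X, params)
            approx = pc.approx_coefficients(grid, params, RHO_X)
            interior = _interior(grid, params, depth=8.0)
            return (
                np.abs(full.delta_ee - approx.delta_ee)[interior]
                / approx.delta_ee[interior]
            ).max()

        assert max_rel(0.02) < max_rel(0.04)


def test_second_moments_reproduce_mutation_scale(fine_kernel):
    kernel, params = fine_kernel
    grid = kernel.grid
    for eta, zeta in [(0.0, 1.0), (0.3, 0.8), (-0.5, 1.3)]:
        m2e, m2z = pc.kernel_second_moments(kernel, grid.nearest_node(eta, zeta))
        assert m2e == pytest.approx(params.eps_eta**2 / 2, rel=0.01)
        assert m2z == pytest.approx(params.eps_zeta**2 / 2, rel=0.01)
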