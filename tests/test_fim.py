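"""Fisher information, gradients, D-objective and D-efficiency."""

import numpy as np
import pytest

from immunodesign import (
    CurveParameters,
    Design,
    ErrorModel,
    ar1_covariance,
    d_efficiency,
    d_objective,
    fisher_information,
    mean_gradient,
)
from immunodesign.fim import FastDObjective
from immunodesign.kinetics import beta_density


class TestAr1Covariance:
    def test_two_by_two(self):
        cov = ar1_covariance(2, ErrorModel(sigma=0.25, rho=0.73))
        assert np.allclose(cov, [[0.0625, 0.045625], [0.045625, 0.0625]])

    def test_independence_gives_identity(self):
        assert np.allclose(ar1_covariance(3, ErrorModel(sigma=1, rho=0)), np.eye(3))

    def test_inverse_is_tridiagonal(self):
        # the AR(1) precision matrix has no entries beyond the first
        # off-diagonal - a classic signature of the process
        prec = np.linalg.inv(ar1_covariance(4, ErrorModel(sigma=0.25, rho=0.73)))
        off = np.triu(prec, k=2)
        assert np.allclose(off, 0, atol=1e-12)

    def test_positive_definite(self):
        cov = ar1_covariance(6, ErrorModel(sigma=0.5, rho=-0.9))
        assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestMeanGradient:
    def test_matches_finite_differences(self, scen9_params):
        # oracle: central differences of the curve in each parameter
        p = scen9_params
        t = 50.0
        grad = mean_gradient(t, p, include_c=True)

        def mu(alpha, beta, ts, c):
            x = (t + c) / ts
            return beta_density(x, alpha, beta)

        theta = [p.alpha, p.beta, p.t_scale, p.c]
        for i in range(4):
            h = 1e-6 * max(abs(theta[i]), 1e-3)
            up = theta.copy(); up[i] += h
            dn = theta.copy(); dn[i] -= h
            fd = (mu(*up) - mu(*dn)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-5)

    def test_matches_finite_differences_without_shift(self, scen1_params):
        p = scen1_params
        t = 120.0
        grad = mean_gradient(t, p, include_c=False)
        theta = [p.alpha, p.beta, p.t_scale]

        def mu(alpha, beta, ts):
            return beta_density(t / ts, alpha, beta)

        for i in range(3):
            h = 1e-6 * max(abs(theta[i]), 1e-3)
            up = theta.copy(); up[i] += h
            dn = theta.copy(); dn[i] -= h
            fd = (mu(*up) - mu(*dn)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-5)

    def test_shape_symmetry_at_midpoint(self):
        # with alpha = beta and x = 1/2 the two shape derivatives coincide
        p = CurveParameters(alpha=3.0, beta=3.0, t_scale=100.0, c=0.0)
        g = mean_gradient(50.0, p, include_c=False)
        assert g[0] == pytest.approx(g[1], rel=1e-12)

    def test_nonzero_at_curve_peak(self, scen1_params, scen1_info):
        # d(mu)/d(theta) need not vanish where d(mu)/dt does
        g = mean_gradient(scen1_info.tmax, scen1_params, include_c=False)
        assert np.max(np.abs(g)) > 0


class TestFisherInformation:
    def brute_force(self, times, params, error, include_c):
        # oracle: explicit double loop over matrix entries
        J = np.array([mean_gradient(t, params, include_c) for t in times])
        sigma_inv = np.linalg.inv(ar1_covariance(len(times), error))
        p = J.shape[1]
        fim = np.zeros((p, p))
        for i in range(p):
            for j in range(p):
                acc = 0.0
                for k in range(len(times)):
                    for l in range(len(times)):
                        acc += J[k, i] * sigma_inv[k, l] * J[l, j]
                fim[i, j] = acc
        return fim

    def test_matches_brute_force(self, scen9_params, error_model):
        times = [2.0, 40.0, 120.0, 300.0]
        design = Design(times=tuple(times))
        fim = fisher_information(design, scen9_params, error_model)
        brute = self.brute_force(times, scen9_params, error_model, True)
        assert np.allclose(fim, brute, rtol=1e-10, atol=1e-10)

    def test_duplicate_times_are_singular(self, scen1_params, error_model):
        design = Design(times=(30.0, 30.0, 200.0))
        fim = fisher_information(design, scen1_params, error_model)
        assert np.linalg.det(fim) == pytest.approx(0, abs=1e-6)

    def test_scales_with_inverse_variance(self, scen1_params):
        design = Design(times=(5.0, 30.0, 180.0))
        f1 = fisher_information(design, scen1_params, ErrorModel(sigma=1.0, rho=0.73))
        f2 = fisher_information(design, scen1_params, ErrorModel(sigma=0.5, rho=0.73))
        assert np.allclose(f2, 4 * f1, rtol=1e-12)

    def test_determinant_identity_square_case(self, scen1_params, error_model):
        # n = p: det(J' S^-1 J) = det(J)^2 det(S^-1)
        times = (3.0, 33.0, 190.0)
        design = Design(times=times)
        J = mean_gradient(np.array(times), scen1_params, include_c=False)
        sigma = ar1_covariance(3, error_model)
        expected = np.linalg.det(J) ** 2 / np.linalg.det(sigma)
        fim = fisher_information(design, scen1_params, error_model)
        assert np.linalg.det(fim) == pytest.approx(expected, rel=1e-10)


class TestDObjective:
    def test_degenerate_design_maps_to_zero(self, scen1_params, error_model):
        design = Design(times=(30.0, 30.0, 200.0))
        assert d_objective(design, scen1_params, error_model) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_informative_design_is_negative(self, scen1_params, error_model):
        design = Design(times=(1.0, 30.0, 200.0))
        assert d_objective(design, scen1_params, error_model) < 0

    def test_optimum_beats_start_design(self, scen1_design, scen1_params,
                                        scen1_info, error_model):
        start = Design(times=(1.0, scen1_info.tmax, scen1_info.tplat))
        assert scen1_design.objective <= d_objective(
            start, scen1_params, error_model
        )

    def test_fast_objective_matches_public_op(self, scen9_params, error_model):
        fast = FastDObjective(scen9_params, error_model)
        times = np.array([0.5, 20.0, 100.0, 340.0])
        public = d_objective(Design(times=tuple(times)), scen9_params, error_model)
        assert fast(times) == pytest.approx(public, rel=1e-12)


class TestDEfficiency:
    def test_identity(self, scen1_design, scen1_params, error_model):
        assert d_efficiency(
            scen1_design.design, scen1_design.design, scen1_params, error_model
        ) == pytest.approx(1.0)

    def test_duplicated_time_gives_zero(self, scen1_design, scen1_params, error_model):
        cand = Design(times=(30.0, 30.0, 200.0))
        assert d_efficiency(
            cand, scen1_design.design, scen1_params, error_model
        ) == pytest.approx(0.0, abs=1e-12)

    def test_equidistant_design_is_suboptimal(self, scen1_design, scen1_params,
                                              error_model):
        # the naive evenly-spaced schedule loses real information
        cand = Design(times=(91.25, 182.5, 273.75))
        eff = d_efficiency(cand, scen1_design.design, scen1_params, error_model)
        assert 0 < eff < 1

    def test_scale_free_in_sigma(self, scen1_design, scen1_params):
        cand = Design(times=(10.0, 60.0, 250.0))
        effs = [
            d_efficiency(cand, scen1_design.design, scen1_params,
                         ErrorModel(sigma=s, rho=0.73))
            for s in (0.1, 0.25, 2.0)
        ]
        assert np.allclose(effs, effs[0], rtol=1e-9)

    def test_singular_reference_is_error(self, scen1_params, error_model):
        bad = Design(times=(30.0, 30.0, 200.0))
        cand = Design(times=(1.0, 30.0, 200.0))
        with pytest.raises(ValueError):
            d_efficiency(cand, bad, scen1_params, error_model)
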