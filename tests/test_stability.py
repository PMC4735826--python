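"""Hopf classification per harmonic and Lyapunov perturbation analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connharm as ch
from connharm.errors import InvalidInputError
from connharm.neuralfield import NeuralFieldParams, simulate
from connharm.stability import (
    classify_cell,
    fixed_point,
    hopf_region_map,
    jacobian_per_harmonic,
    lyapunov_test,
    perturbation_growth_rate,
)


class TestFixedPoint:
    def test_zero_coupling_closed_form(self):
        p = NeuralFieldParams(alpha_ee=0, alpha_ie=0, alpha_ei=0, alpha_ii=0)
        E, I = fixed_point(p)
        assert E == pytest.approx(0.25, abs=1e-12)  # S(0)/d_E with d_E = 2
        assert I == pytest.approx(0.25, abs=1e-12)

    def test_residual_contract(self):
        from connharm.neuralfield import sigmoid

        p = NeuralFieldParams.preset("slow_excitation")
        E, I = fixed_point(p)
        r1 = -p.d_e * E + sigmoid(p.alpha_ee * E - p.alpha_ie * I)
        r2 = -p.d_i * I + sigmoid(p.alpha_ei * E - p.alpha_ii * I)
        assert max(abs(r1), abs(r2)) < 1e-10

    def test_matches_long_time_simulation_in_stable_regime(self, ring32_laplacian):
        p = NeuralFieldParams(
            alpha_ee=20, alpha_ie=20, alpha_ei=20, alpha_ii=20, t_end=30.0, seed=3
        )
        res = simulate(ring32_laplacian, p)
        E, I = fixed_point(p)
        assert np.abs(res.E[:, -1] - E).max() < 1e-3
        assert np.abs(res.I[:, -1] - I).max() < 1e-3


class TestJacobian:
    def test_lambda_zero_reduces_to_spaceless_pair(self):
        from connharm.neuralfield import sigmoid_deriv

        p = NeuralFieldParams.preset("slow_excitation")
        E, I = fixed_point(p)
        J = jacobian_per_harmonic(p, 0.0, lam_max=2.0, fixed_pt=(E, I))
        se = sigmoid_deriv(p.alpha_ee * E - p.alpha_ie * I)
        si = sigmoid_deriv(p.alpha_ei * E - p.alpha_ii * I)
        expect = np.array(
            [
                [-p.d_e + p.alpha_ee * se, -p.alpha_ie * se],
                [p.alpha_ei * si, -p.d_i - p.alpha_ii * si],
            ]
        )
        assert np.abs(J - expect).max() < 1e-12

    def test_equal_sigmas_give_equal_gains(self):
        p = NeuralFieldParams(sigma_ee=5, sigma_ei=5, sigma_ie=5, sigma_ii=5)
        from connharm.stability import _gains

        g = _gains(p, lam=0.3, lam_max=2.0)
        assert len(set(g.values())) == 1

    def test_finite_difference_oracle(self, ring32_laplacian):
        # the analytic 2x2 block must match a numerically differentiated
        # full-system Jacobian projected onto (psi_j x psi_j)
        from connharm.neuralfield import _rhs, build_operators

        p = NeuralFieldParams.preset("slow_excitation")
        basis = ch.compute_harmonics(ring32_laplacian, 12)
        ops = build_operators(ring32_laplacian, p)
        fp = fixed_point(p)
        E0, I0 = np.full(32, fp[0]), np.full(32, fp[1])
        h = 1e-6
        for j in (1, 5, 11):
            psi = basis.eigenvectors[:, j]
            cols = []
            for dE, dI in ((psi, 0 * psi), (0 * psi, psi)):
                fE_p, fI_p = _rhs(E0 + h * dE, I0 + h * dI, ops, p)
                fE_m, fI_m = _rhs(E0 - h * dE, I0 - h * dI, ops, p)
                cols.append([psi @ (fE_p - fE_m) / (2 * h), psi @ (fI_p - fI_m) / (2 * h)])
            J_num = np.array(cols).T
            J = jacobian_per_harmonic(
                p, float(basis.eigenvalues[j]), ring32_laplacian.lambda_max_bound(), fixed_pt=fp
            )
            assert np.abs(J - J_num).max() < 1e-6


class TestClassification:
    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(-5, 5, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
    )
    def test_consistent_with_direct_eigenvalues(self, a, b, c, d):
        from hypothesis import assume

        J = np.array([[a, b], [c, d]])
        tr, det = np.trace(J), np.linalg.det(J)
        # keep away from the stability boundaries, where the discrete
        # classification is tolerance-dependent by design
        assume(abs(tr) > 1e-6 and abs(det) > 1e-6 and abs(tr**2 - 4 * det) > 1e-6)
        cls = classify_cell(tr, det, tau_s=1.0, hopf_tol=1e-9)
        ev = np.linalg.eigvals(J)
        re = ev.real.max()
        if cls == "stable":
            assert re < 1e-9
        elif cls == "unstable_oscillatory":
            assert re > 0 and abs(ev.imag).max() > 0
        elif cls == "unstable_monotonic":
            assert re > -1e-9 and (det < 0 or abs(ev.imag).max() == 0)

    def test_zero_coupling_map_all_stable(self):
        p = NeuralFieldParams(alpha_ee=0, alpha_ie=0, alpha_ei=0, alpha_ii=0)
        m = hopf_region_map(p, "sigma_ii", [10, 50, 90], [0.0, 0.5, 1.0, 2.0])
        assert (m.classification == "stable").all()
        assert (m.trace < 0).all()

    def test_grid_order_invariance(self):
        p = NeuralFieldParams.preset("slow_excitation")
        lams = np.array([0.1, 0.5, 1.0])
        m1 = hopf_region_map(p, "sigma_ee", [2.0, 6.0, 20.0], lams, lam_max=2.0)
        m2 = hopf_region_map(p, "sigma_ee", [20.0, 2.0, 6.0], lams, lam_max=2.0)
        assert (m1.classification[[0, 1, 2]] == m2.classification[[1, 2, 0]]).all()

    def test_unknown_sweep_parameter_rejected(self):
        with pytest.raises(InvalidInputError):
            hopf_region_map(NeuralFieldParams(), "sigma_xx", [1.0], [0.1])

    def test_hopf_critical_detected_on_trace_zero_line(self):
        p = NeuralFieldParams.preset("slow_excitation")
        m = hopf_region_map(p, "sigma_ee", [6.0], [0.2], lam_max=2.0, hopf_tol=10.0)
        # with an absurdly wide tolerance everything with det>0 is "critical"
        assert m.classification[0, 0] == "hopf_critical"


class TestGrowthCrossCheck:
    def test_prediction_matches_simulation_sign(self, ring32_laplacian):
        p = NeuralFieldParams.preset("slow_excitation", scheme="rk4")
        basis = ch.compute_harmonics(ring32_laplacian, 12)
        lam_max = ring32_laplacian.lambda_max_bound()
        fp = fixed_point(p)
        for j in (1, 2, 6):
            lam = float(basis.eigenvalues[j])
            J = jacobian_per_harmonic(p, lam, lam_max, fixed_pt=fp)
            pred = np.linalg.eigvals(J).real.max()
            rate = perturbation_growth_rate(
                ring32_laplacian, p, basis.eigenvectors[:, j], lam, eps=1e-5, t_end=2.0
            )
            assert (pred > 0) == (rate > 0)
            assert rate == pytest.approx(pred, abs=0.2 + 0.05 * abs(pred))


class TestLyapunov:
    def test_zero_noise_gives_identically_zero(self, ring32_laplacian):
        p = NeuralFieldParams.preset("slow_excitation", t_end=6.0, seed=1)
        res = lyapunov_test(ring32_laplacian, p, t_star=3.0, n_perturb=3, noise_amp=0.0)
        assert (res.L == 0).all()
        assert res.verdict

    def test_default_protocol_uses_ten_perturbations(self, ring32_laplacian):
        import inspect

        assert inspect.signature(lyapunov_test).parameters["n_perturb"].default == 10

    def test_zero_before_tstar_and_bounded_after(self, ring32_laplacian):
        p = NeuralFieldParams.preset("slow_excitation", t_end=30.0, seed=5)
        res = lyapunov_test(
            ring32_laplacian, p, t_star=15.0, n_perturb=4, seed=11
        )
        pre = res.t < 15.0
        assert (res.L[pre] == 0).all()
        assert np.isfinite(res.sup_L)
        assert res.L[~pre][1:].max() > 0
        assert res.noise_amp > 0

    def test_invalid_tstar_rejected(self, ring32_laplacian):
        p = NeuralFieldParams(t_end=5.0)
        with pytest.raises(InvalidInputError):
            lyapunov_test(ring32_laplacian, p, t_star=5.0)
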