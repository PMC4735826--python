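"""Wilson-Cowan dynamics on graphs: diffusion operators, integration, spectra."""

import numpy as np
import pytest

import connharm as ch
from connharm.errors import InvalidInputError, NumericalError
from connharm.neuralfield import (
    DiffusionOperator,
    NeuralFieldParams,
    build_operators,
    dominant_frequency,
    power_spectrum,
    sigmoid,
    simulate,
    substeps_for,
)


class TestSigmoid:
    def test_midpoint_and_saturation(self):
        assert sigmoid(0.7, a=2.0, theta=0.7) == 0.5
        assert sigmoid(1e3) == pytest.approx(1.0)
        assert sigmoid(-1e3) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        assert sigmoid(np.log(3.0)) == pytest.approx(0.75)

    def test_strictly_increasing(self):
        x = np.linspace(-5, 5, 101)
        assert (np.diff(sigmoid(x, a=0.7, theta=1.2)) > 0).all()


class TestDiffusionOperator:
    def test_zero_sigma_is_identity(self, ring32_laplacian, rng):
        u = rng.normal(size=32)
        op = DiffusionOperator(ring32_laplacian, 0.0)
        assert (op.apply(u) == u).all()

    def test_eigenvector_scaling(self, ring32_laplacian):
        basis = ch.compute_harmonics(ring32_laplacian, 32)
        op = DiffusionOperator(ring32_laplacian, 3.0)
        for j in (0, 1, 5, 16):
            psi = basis.eigenvectors[:, j]
            out = op.apply(psi)
            gain = op.gain(basis.eigenvalues[j])
            assert np.abs(out - gain * psi).max() < 1e-9

    def test_combinatorial_preserves_constants(self, ring32_laplacian):
        op = DiffusionOperator(ring32_laplacian, 7.0)
        u = np.full(32, 0.4)
        assert np.abs(op.apply(u) - u).max() < 1e-12

    def test_gain_approximates_heat_kernel(self, ring32_laplacian):
        op = DiffusionOperator(ring32_laplacian, 2.0)
        lam = 0.3
        assert op.gain(lam) == pytest.approx(np.exp(-2.0 * lam), rel=0.05)

    def test_unstable_substepping_rejected(self, ring32_laplacian):
        with pytest.raises(InvalidInputError, match="substep"):
            DiffusionOperator(ring32_laplacian, 10.0, s=2)

    def test_substep_rule(self):
        assert substeps_for(0.0, 8.0) == 1
        s = substeps_for(50.0, 2.0)
        assert (50.0 / s) * 2.0 <= 0.5

    def test_sparse_and_dense_paths_agree(self, ring32_laplacian, rng):
        u = rng.normal(size=32)
        op = DiffusionOperator(ring32_laplacian, 2.0)
        dense = op.apply(u)
        op._dense = None  # force the iterative sparse path
        assert np.abs(op.apply(u) - dense).max() < 1e-10


class TestSimulate:
    def test_zero_coupling_decays_to_closed_form(self, ring32_laplacian):
        # with all alpha = 0 each node obeys tau dE/dt = -d E + S(0):
        # E(t) = S(0)/d + (E0 - S(0)/d) exp(-d t / tau)
        p = NeuralFieldParams(
            alpha_ee=0, alpha_ie=0, alpha_ei=0, alpha_ii=0,
            t_end=4.0, dt=0.002, seed=1,
        )
        res = simulate(ring32_laplacian, p)
        E0 = res.E[:, 0]
        t = res.t[-1]
        expect = 0.25 + (E0 - 0.25) * np.exp(-2.0 * t)
        assert np.abs(res.E[:, -1] - expect).max() < 1e-4

    def test_uniform_init_stays_uniform_on_ring(self, ring32_laplacian):
        # moderate coupling: no unstable modes to amplify float roundoff
        p = NeuralFieldParams(
            alpha_ee=20, alpha_ie=20, alpha_ei=20, alpha_ii=20,
            t_end=3.0, init="constant", init_amplitude=0.2,
        )
        res = simulate(ring32_laplacian, p)
        assert np.ptp(res.E, axis=0).max() < 1e-12  # vertex-transitive symmetry

    def test_trajectories_bounded(self, ring32_laplacian):
        p = NeuralFieldParams.preset("slow_excitation", t_end=20.0, seed=6)
        res = simulate(ring32_laplacian, p)
        assert res.E.min() >= 0.0
        assert res.E.max() <= 1.0 / p.d_e + 1e-6
        assert res.I.max() <= 1.0 / p.d_i + 1e-6

    def test_seed_determinism(self, ring32_laplacian):
        p = NeuralFieldParams.preset("slow_excitation", t_end=2.0, seed=9)
        a = simulate(ring32_laplacian, p)
        b = simulate(ring32_laplacian, p)
        assert (a.E == b.E).all() and (a.I == b.I).all()

    @pytest.mark.parametrize(
        "kw",
        [
            dict(alpha_ee=20, alpha_ie=20, alpha_ei=20, alpha_ii=20, t_end=5.0, dt=0.01),
            dict(sigma_ee=6, sigma_ei=4, sigma_ie=4, sigma_ii=50, scheme="rk4", t_end=2.0, dt=0.01),
        ],
        ids=["euler_moderate_coupling", "rk4_oscillatory"],
    )
    def test_dt_halving_convergence(self, ring32_laplacian, kw):
        p = NeuralFieldParams(seed=4, **kw)
        r1 = simulate(ring32_laplacian, p)
        r2 = simulate(ring32_laplacian, p.replace(dt=p.dt / 2))
        assert np.abs(r1.E[:, -1] - r2.E[:, -1]).max() < 1e-3

    def test_linearized_simulation_matches_modal_integration(self, ring32_laplacian):
        # tiny perturbations of the uniform fixed point evolve per harmonic
        # under the 2x2 Jacobian; compare full nonlinear integration with the
        # diagonalized linear solution
        from connharm.stability import fixed_point, jacobian_per_harmonic
        import scipy.linalg

        p = NeuralFieldParams.preset("slow_excitation", scheme="rk4", dt=0.001, t_end=0.5)
        basis = ch.compute_harmonics(ring32_laplacian, 32)
        fp = fixed_point(p)
        eps = 1e-9  # small enough that second-order terms stay negligible
        coeff = np.zeros(32)
        coeff[[1, 4, 9]] = [1.0, -0.5, 0.25]
        psi_mix = basis.eigenvectors @ coeff
        res = simulate(
            ring32_laplacian,
            p.replace(init="given"),
            init_state=(fp[0] + eps * psi_mix, np.full(32, fp[1])),
        )
        lam_max = ring32_laplacian.lambda_max_bound()
        for j in (1, 4, 9):
            J = jacobian_per_harmonic(p, float(basis.eigenvalues[j]), lam_max, fixed_pt=fp)
            expect = scipy.linalg.expm(J * res.t[-1]) @ np.array([eps * coeff[j], 0.0])
            got_E = basis.eigenvectors[:, j] @ (res.E[:, -1] - fp[0])
            got_I = basis.eigenvectors[:, j] @ (res.I[:, -1] - fp[1])
            assert np.abs(np.array([got_E, got_I]) - expect).max() < 1e-4 * eps

    def test_invalid_time_step_rejected(self):
        with pytest.raises(InvalidInputError):
            NeuralFieldParams(dt=1.5, tau_s=1.0)  # dt >= tau_s


class TestPowerSpectrum:
    def _result_from_series(self, X, dt=0.05):
        t = np.arange(X.shape[1]) * dt
        p = NeuralFieldParams(dt=dt, t_end=t[-1])
        from connharm.neuralfield import SimulationResult

        return SimulationResult(E=X, I=np.zeros_like(X), t=t, params=p)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        dt, f0 = 0.05, 1.25
        t = np.arange(400) * dt
        X = np.tile(np.sin(2 * np.pi * f0 * t), (3, 1))
        res = self._result_from_series(X, dt)
        freqs, power = power_spectrum(res, transient_frac=0.0)
        assert freqs[np.argmax(power)] == pytest.approx(f0, abs=freqs[1])
        assert dominant_frequency(res, transient_frac=0.0) == pytest.approx(f0, abs=freqs[1])

    def test_constant_signal_has_only_dc_power(self):
        X = np.full((2, 128), 0.3)
        freqs, power = power_spectrum(self._result_from_series(X), transient_frac=0.0)
        assert power[0] > 0
        assert np.abs(power[1:]).max() < 1e-25

    def test_too_short_series_rejected(self, ring32_laplacian):
        p = NeuralFieldParams(t_end=0.02, dt=0.01)
        res = simulate(ring32_laplacian, p)
        with pytest.raises(InvalidInputError):
            power_spectrum(res, transient_frac=0.9)


class TestSeedCorrelation:
    def test_self_identical_and_sign_flip(self):
        t = np.linspace(0, 10, 200)
        base = np.sin(t)
        X = np.vstack([base, base, -base, np.full_like(t, 0.5)])
        from connharm.neuralfield import SimulationResult

        res = SimulationResult(E=X, I=np.zeros_like(X), t=t, params=NeuralFieldParams(t_end=10.0, dt=0.05))
        corr = ch.seed_correlation(res, [0], transient_frac=0.0)[0]
        assert corr[0] == pytest.approx(1.0)
        assert corr[1] == pytest.approx(1.0)
        assert corr[2] == pytest.approx(-1.0)
        assert np.isnan(corr[3])  # zero-variance node flagged, not zeroed

    def test_correlation_decays_with_ring_distance(self, ring32_laplacian):
        p = NeuralFieldParams.preset("slow_excitation", t_end=40.0, seed=2)
        res = simulate(ring32_laplacian, p)
        corr = ch.seed_correlation(res, [0])[0]
        d = np.minimum(np.arange(32), 32 - np.arange(32))
        # monotone decrease with graph distance over the half ring
        import scipy.stats

        rho = scipy.stats.spearmanr(d[1:17], corr[1:17]).statistic
        assert rho < -0.95

    def test_out_of_range_seed_rejected(self, ring32_laplacian):
        p = NeuralFieldParams(t_end=1.0)
        res = simulate(ring32_laplacian, p)
        with pytest.raises(InvalidInputError):
            ch.seed_correlation(res, [32])
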