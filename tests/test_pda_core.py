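import numpy as np
import pytest

from odeseq.basis import FourierBasis
from odeseq.pda import (
    OdeCoefficients,
    estimate_coefficients,
    fit_pda,
    ode_penalty_matrix,
    select_lambda,
    smooth_states,
    sse_penalty,
)

OMEGA = 2 * np.pi / 100.0


def _curves(make_curve, ys, t=None):
    return [make_curve(y, t=t, sample_id=f"s{i}") for i, y in enumerate(ys)]


class TestPenaltyMatrix:
    def test_zero_operator_reduces_to_curvature_penalty(self, basis11):
        J = ode_penalty_matrix(basis11)
        D2 = basis11.grid_matrix(2)
        expected = basis11.inner_product(D2, D2)
        assert np.allclose(J, expected, atol=1e-12)
        # constant basis function has zero second derivative
        assert np.allclose(J[0, :], 0.0, atol=1e-12)
        assert np.allclose(J[:, 0], 0.0, atol=1e-12)

    def test_zero_operator_diagonal_closed_form(self):
        # with h = 0, J = int phi'' phi''^T dt = diag(omega_r^4) by
        # orthonormality of the Fourier system
        bs = FourierBasis(n_basis=5)
        J = ode_penalty_matrix(bs)
        expected = np.diag(
            [0.0, OMEGA**4, OMEGA**4, (2 * OMEGA) ** 4, (2 * OMEGA) ** 4]
        )
        assert np.allclose(J, expected, rtol=1e-8, atol=1e-12)

    def test_psd_for_random_operators(self, basis11):
        rng = np.random.default_rng(7)
        for _ in range(100):
            co = OdeCoefficients(
                h0=rng.normal(scale=0.1, size=11),
                h1=rng.normal(scale=0.1, size=11),
                basis=basis11,
            )
            J = ode_penalty_matrix(basis11, co)
            assert np.allclose(J, J.T)
            assert np.min(np.linalg.eigvalsh(J)) >= -1e-10


class TestSmoothing:
    def test_unpenalized_fit_is_exact_on_span(self, basis11, make_curve):
        t = np.linspace(0, 100, 200)
        rng = np.random.default_rng(3)
        c_true = rng.normal(size=11)
        y = basis11.evaluate(t, 0) @ c_true
        fit = smooth_states([make_curve(y, t=t)], basis11, None, lam=0.0)
        assert np.allclose(fit.C[0], c_true, atol=1e-9)
        assert fit.rss[0] < 1e-18

    def test_pure_sine_projects_to_single_coefficient(self, basis11, make_curve):
        t = np.linspace(0, 100, 200)
        y = np.sin(OMEGA * t)
        fit = smooth_states([make_curve(y, t=t)], basis11, None, lam=0.0)
        c = fit.C[0].copy()
        # column 1 is sin(2 pi t / 100); amplitude sqrt(2/100)
        assert c[1] == pytest.approx(np.sqrt(100 / 2.0), rel=1e-10)
        c[1] = 0.0
        assert np.max(np.abs(c)) < 1e-8

    def test_huge_lambda_flattens_to_constant(self, basis11, make_curve):
        t = np.linspace(0, 100, 200)
        rng = np.random.default_rng(5)
        y = rng.normal(size=t.size)
        fit = smooth_states([make_curve(y, t=t)], basis11, None, lam=1e8)
        xhat = fit.evaluate(0, t)
        # curvature penalty with h=0 leaves only the constant direction free
        assert np.max(np.abs(xhat - xhat.mean())) < 1e-3
        assert xhat.mean() == pytest.approx(y.mean(), rel=1e-3)

    def test_underdetermined_unpenalized_fit_rejected(self, basis11, make_curve):
        t = np.linspace(0, 100, 8)
        with pytest.raises(np.linalg.LinAlgError, match="raise lam"):
            smooth_states([make_curve(np.ones(8), t=t)], basis11, None, lam=0.0)

    def test_negative_lambda_rejected(self, basis11, make_curve):
        with pytest.raises(ValueError):
            smooth_states([make_curve(np.ones(10))], basis11, None, lam=-1.0)


class TestEstimateCoefficients:
    def test_harmonic_pair_recovers_constant_operator(self, basis11, make_curve):
        # sin and cos both solve x'' + omega^2 x = 0 exactly and lie in-span
        t = np.linspace(0, 100, 200)
        curves = _curves(make_curve, [np.sin(OMEGA * t), np.cos(OMEGA * t)], t=t)
        fit = smooth_states(curves, basis11, None, lam=0.0)
        co = estimate_coefficients(fit, basis11)
        tc = np.linspace(10, 90, 200)
        assert np.max(np.abs(co.w0(tc) - OMEGA**2)) < 1e-3 * OMEGA**2
        assert np.max(np.abs(co.w1(tc))) < 1e-10

    def test_constant_curve_gives_zero_w0(self, basis11, make_curve):
        t = np.linspace(0, 100, 150)
        fit = smooth_states([make_curve(np.full(t.size, 3.0), t=t)], basis11, None, 0.0)
        co = estimate_coefficients(fit, basis11)
        tc = np.linspace(0, 100, 101)
        assert np.max(np.abs(co.w0(tc))) < 1e-8
        assert np.max(np.abs(co.w1(tc))) < 1e-8

    def test_first_order_decay_family_silences_w0(self, basis21, make_curve):
        # family of x'' + a x' = 0: constants plus exp(-a t)
        a = 1 / 20.0
        t = np.linspace(0, 100, 201)
        ys = [c1 + c2 * np.exp(-a * t) for c1, c2 in [(1, 1), (0.5, -2), (2, 0.5)]]
        res = fit_pda(_curves(make_curve, ys, t=t), basis=basis21, lam=1e2, max_iter=50)
        tc = np.linspace(10, 90, 200)
        assert np.median(np.abs(res.coefficients.w0(tc))) < 0.01
        # the operator residual must have dropped relative to the zero operator
        fit0 = smooth_states(_curves(make_curve, ys, t=t), basis21, None, 0.0)
        sse0 = sse_penalty(fit0, OdeCoefficients.zero(basis21))
        assert res.sse_path[-1] < sse0

    def test_all_zero_states_rejected(self, basis11):
        from odeseq.pda import StateFit

        fit = StateFit(C=np.zeros((2, 11)), basis=basis11, lam=0.0, rss=np.zeros(2))
        with pytest.raises(ValueError, match="no signal"):
            estimate_coefficients(fit, basis11)


class TestFitPda:
    def test_infinite_tol_is_single_pass(self, basis11, make_curve):
        t = np.linspace(0, 100, 200)
        curves = _curves(make_curve, [np.sin(OMEGA * t), np.cos(OMEGA * t)], t=t)
        res = fit_pda(curves, basis=basis11, lam=0.0, tol=np.inf)
        assert res.n_iter == 1
        one_fit = smooth_states(curves, basis11, None, 0.0)
        one_co = estimate_coefficients(one_fit, basis11)
        assert np.allclose(res.coefficients.h, one_co.h)

    def test_in_span_ode_family_converges_fast(self, basis11, make_curve):
        t = np.linspace(0, 100, 200)
        curves = _curves(make_curve, [np.sin(OMEGA * t), np.cos(OMEGA * t)], t=t)
        res = fit_pda(curves, basis=basis11, lam=1.0, tol=1e-10)
        assert res.converged
        assert res.n_iter <= 10
        assert res.sse_path[-1] < 1e-6

    def test_penalty_identity(self, basis11, make_curve):
        # lam * C^T J C equals lam * int L(xhat)^2 dt
        t = np.linspace(0, 100, 200)
        rng = np.random.default_rng(11)
        curves = _curves(make_curve, rng.normal(size=(3, t.size)), t=t)
        res = fit_pda(curves, basis=basis11, lam=10.0, max_iter=5, tol=np.inf)
        J = ode_penalty_matrix(basis11, res.coefficients)
        quad_form = sum(c @ J @ c for c in res.states.C)
        assert quad_form == pytest.approx(
            sse_penalty(res.states, res.coefficients), rel=1e-8, abs=1e-12
        )

    def test_offset_equivariance(self, basis11, make_curve):
        t = np.linspace(0, 100, 200)
        rng = np.random.default_rng(13)
        y = rng.normal(size=t.size)
        base = smooth_states([make_curve(y, t=t)], basis11, None, lam=50.0)
        shifted = smooth_states([make_curve(y + 2.5, t=t)], basis11, None, lam=50.0)
        # with h=0 the constant direction is unpenalized, so the fit shifts
        assert np.allclose(
            shifted.evaluate(0, t), base.evaluate(0, t) + 2.5, atol=1e-8
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_pda([])

    def test_nonpositive_tol_rejected(self, make_curve):
        with pytest.raises(ValueError):
            fit_pda([make_curve(np.ones(10))], tol=0.0)


class TestSelectLambda:
    def _family(self, make_curve, n=6, noise=0.0, seed=0):
        t = np.linspace(0, 100, 120)
        rng = np.random.default_rng(seed)
        ys = [
            a * np.sin(OMEGA * t) + b * np.cos(OMEGA * t) + rng.normal(0, noise, t.size)
            for a, b in rng.normal(size=(n, 2))
        ]
        return _curves(make_curve, ys, t=t)

    def test_single_element_grid(self, make_curve):
        curves = self._family(make_curve)
        assert select_lambda(curves, 11, [3.14], folds=2) == 3.14

    def test_noiseless_in_span_prefers_smallest(self, make_curve):
        curves = self._family(make_curve)
        lam = select_lambda(curves, 11, [1e-3, 1.0, 1e3], folds=3, seed=1)
        assert lam == 1e-3

    def test_deterministic_given_seed(self, make_curve):
        curves = self._family(make_curve, noise=0.2, seed=4)
        grid = [0.1, 1.0, 10.0]
        assert select_lambda(curves, 11, grid, seed=9) == select_lambda(
            curves, 11, grid, seed=9
        )

    def test_too_few_samples_rejected(self, make_curve):
        curves = self._family(make_curve, n=3)
        with pytest.raises(ValueError, match="folds"):
            select_lambda(curves, 11, [1.0], folds=5)

    def test_empty_grid_rejected(self, make_curve):
        with pytest.raises(ValueError):
            select_lambda(self._family(make_curve), 11, [])


class TestRecovery:
    def test_recovery_from_default_truth_small_n(self):
        from odeseq.simulate import SimulationSpec, default_w0, default_w1, generate_curves

        spec = SimulationSpec(noise_sd=0.0, n_samples=10, seed=5)
        curves, _, _ = generate_curves(spec)
        res = fit_pda(curves, n_basis=21, lam=1e3)
        tc = np.linspace(10, 90, 400)
        co = res.coefficients
        num = np.trapezoid(
            (co.w0(tc) - default_w0(tc)) ** 2 + (co.w1(tc) - default_w1(tc)) ** 2, tc
        )
        den = np.trapezoid(default_w0(tc) ** 2 + default_w1(tc) ** 2, tc)
        assert np.sqrt(num / den) <= 0.10
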