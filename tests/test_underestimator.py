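import numpy as np
import pytest

from ssdu.underestimator import (
    PolyUnderestimator,
    UnderestimatorError,
    evaluate,
    fit_underestimator,
    gradient,
    hessian,
    is_sos_convex,
    minimize_convex,
    monomial_basis,
)


def quad_coeffs(A, b, c, n=3):
    """Coefficient vector of phi'A phi + b'phi + c over the degree-2 basis."""
    exps = monomial_basis(n, 2)
    out = np.zeros(len(exps))
    idx = {e: k for k, e in enumerate(exps)}
    out[idx[tuple([0] * n)]] = c
    for p in range(n):
        e = [0] * n
        e[p] = 1
        out[idx[tuple(e)]] = b[p]
        e[p] = 2
        out[idx[tuple(e)]] = A[p, p]
        for q in range(p + 1, n):
            e = [0] * n
            e[p] = e[q] = 1
            out[idx[tuple(e)]] = 2 * A[p, q]
    return out, exps


class TestMonomialBasis:
    @pytest.mark.parametrize("n,d,length", [(1, 1, 2), (2, 2, 6), (3, 4, 35), (3, 2, 10)])
    def test_lengths_match_stars_and_bars(self, n, d, length):
        basis = monomial_basis(n, d)
        assert len(basis) == length
        assert len(set(basis)) == length
        degs = [sum(e) for e in basis]
        assert degs == sorted(degs)  # graded order


class TestCalculus:
    def test_norm_squared_closed_form(self):
        c, exps = quad_coeffs(np.eye(3), np.zeros(3), 0.0)
        U = PolyUnderestimator(n=3, degree=2, coeffs=c, exponents=exps)
        p = np.ones(3)
        assert evaluate(U, p) == pytest.approx(3.0)
        assert np.allclose(gradient(U, p), [2, 2, 2])
        assert np.allclose(hessian(U, p), 2 * np.eye(3))

    def test_gradient_matches_finite_differences(self, rng):
        exps = monomial_basis(3, 4)
        for _ in range(5):
            U = PolyUnderestimator(n=3, degree=4, coeffs=rng.normal(size=len(exps)),
                                   exponents=exps)
            phi = rng.normal(size=3)
            g = gradient(U, phi)
            h = 1e-6
            for p in range(3):
                e = np.zeros(3)
                e[p] = h
                fd = (evaluate(U, phi + e) - evaluate(U, phi - e)) / (2 * h)
                assert g[p] == pytest.approx(fd, rel=1e-5, abs=1e-5)
            H = hessian(U, phi)
            assert np.array_equal(H, H.T)


class TestFit:
    def test_exact_recovery_of_convex_quadratic(self, rng):
        P = rng.normal(size=(120, 3))
        f = 1.0 + np.sum(P**2, axis=1)
        U = fit_underestimator(P, f, degree=2)
        c_true, _ = quad_coeffs(np.eye(3), np.zeros(3), 1.0)
        assert np.allclose(U.coeffs, c_true, atol=1e-5)
        assert U.fit_report["total_gap"] <= 1e-6 * len(f)

    def test_constant_energies_give_constant_fit(self, rng):
        P = rng.normal(size=(60, 3))
        f = np.full(60, 4.2)
        U = fit_underestimator(P, f, degree=4)
        vals = evaluate(U, P)
        assert np.max(np.abs(vals - 4.2)) < 1e-4

    def test_underestimation_feasibility_on_rugged_data(self, rng):
        P = rng.normal(size=(150, 3))
        f = np.sum(P**2, axis=1) + 0.7 * np.sin(3.0 * P).sum(axis=1)
        U = fit_underestimator(P, f, degree=4)
        gaps = f - evaluate(U, P)
        assert gaps.min() >= -1e-6
        assert U.sos_certificate["min_eig"] >= -1e-7

    def test_degree_four_at_least_as_tight_as_degree_two(self, rng):
        P = rng.normal(size=(100, 3))
        f = np.sum(P**4, axis=1) + np.sin(2 * P).sum(axis=1)
        g2 = fit_underestimator(P, f, degree=2).fit_report["total_gap"]
        g4 = fit_underestimator(P, f, degree=4).fit_report["total_gap"]
        assert g4 <= g2 * (1 + 1e-6) + 1e-6

    def test_energy_shift_equivariance(self, rng):
        P = rng.normal(size=(80, 3))
        f = np.sum(P**2, axis=1) + np.sin(2 * P).sum(axis=1)
        U0 = fit_underestimator(P, f, degree=2)
        U1 = fit_underestimator(P, f + 5.0, degree=2)
        d = U1.coeffs - U0.coeffs
        assert d[0] == pytest.approx(5.0, abs=1e-5)
        assert np.allclose(d[1:], 0.0, atol=1e-5)

    def test_translation_equivariance_of_minimizer(self, rng):
        P = rng.normal(size=(80, 3))
        f = np.sum((P - 0.3) ** 2, axis=1) + 0.3 * np.sin(4 * P).sum(axis=1)
        t = np.array([1.0, -2.0, 0.5])
        U0 = fit_underestimator(P, f, degree=4)
        U1 = fit_underestimator(P + t, f, degree=4)
        x0, _ = minimize_convex(U0)
        x1, _ = minimize_convex(U1, init=x0 + t)
        assert np.allclose(x1, x0 + t, atol=1e-4)

    def test_underdetermined_fit_warns_but_succeeds(self, rng):
        P = rng.normal(size=(10, 3))
        f = np.sum(P**2, axis=1)
        with pytest.warns(UserWarning, match="underdetermined"):
            U = fit_underestimator(P, f, degree=4)
        assert (f - evaluate(U, P)).min() >= -1e-6

    def test_degree_six_supported_and_tighter_than_degree_four(self, rng):
        P = rng.normal(size=(100, 3))
        f = np.sum(P**2, axis=1) + 0.5 * np.sin(3 * P).sum(axis=1)
        U6 = fit_underestimator(P, f, degree=6)
        assert (f - evaluate(U6, P)).min() >= -1e-6
        g4 = fit_underestimator(P, f, degree=4).fit_report["total_gap"]
        assert U6.fit_report["total_gap"] <= g4 * (1 + 1e-9) + 1e-7

    def test_empty_input_rejected(self):
        with pytest.raises(UnderestimatorError):
            fit_underestimator(np.zeros((0, 3)), np.zeros(0))


class TestMinimizeConvex:
    def test_quadratic_minimizer_matches_linear_solve(self, rng):
        B = rng.normal(size=(3, 3))
        A = B @ B.T + 0.5 * np.eye(3)
        b = rng.normal(size=3)
        c, exps = quad_coeffs(A, b, 2.0)
        U = PolyUnderestimator(n=3, degree=2, coeffs=c, exponents=exps)
        x, v = minimize_convex(U, init=rng.normal(size=3))
        ref = np.linalg.solve(2 * A, -b)  # stationarity of phi'A phi + b'phi
        assert np.allclose(x, ref, atol=1e-8)

    def test_init_independence_and_point_minimality(self, rng):
        P = rng.normal(size=(100, 3))
        f = np.sum(P**2, axis=1) + 0.5 * np.sin(3 * P).sum(axis=1)
        U = fit_underestimator(P, f, degree=4)
        x1, v1 = minimize_convex(U, init=np.zeros(3))
        x2, v2 = minimize_convex(U, init=np.array([3.0, -3.0, 3.0]))
        assert np.allclose(x1, x2, atol=1e-5)
        assert v1 <= evaluate(U, P).min() + 1e-9

    def test_unbounded_polynomial_detected(self):
        exps = monomial_basis(3, 2)
        c = np.zeros(len(exps))
        c[1] = -1.0  # U = -phi_1: linear, unbounded below
        U = PolyUnderestimator(n=3, degree=2, coeffs=c, exponents=exps)
        with pytest.raises(UnderestimatorError):
            minimize_convex(U)


class TestSosCertificate:
    def test_norm_fourth_power_certified(self):
        exps = monomial_basis(3, 4)
        idx = {e: k for k, e in enumerate(exps)}
        c = np.zeros(len(exps))
        for p in range(3):
            e = [0, 0, 0]
            e[p] = 4
            c[idx[tuple(e)]] = 1.0
            for q in range(p + 1, 3):
                e = [0, 0, 0]
                e[p] = e[q] = 2
                c[idx[tuple(e)]] = 2.0
        cert = is_sos_convex(PolyUnderestimator(n=3, degree=4, coeffs=c, exponents=exps))
        assert cert is not None
        assert np.linalg.eigvalsh(cert["gram"]).min() >= -1e-7

    def test_concave_quadratic_refused(self):
        c, exps = quad_coeffs(-np.eye(3), np.zeros(3), 0.0)
        U = PolyUnderestimator(n=3, degree=2, coeffs=c, exponents=exps)
        assert is_sos_convex(U) is None

    def test_explicitly_constructed_sos_convex_quartic_certified(self, rng):
        # U = (a'phi)^4 + phi'B B' phi is SOS-convex by construction
        a = rng.normal(size=3)
        B = rng.normal(size=(3, 3))
        exps = monomial_basis(3, 4)
        idx = {e: k for k, e in enumerate(exps)}
        c = np.zeros(len(exps))
        import itertools

        for combo in itertools.product(range(3), repeat=4):
            e = [0, 0, 0]
            w = 1.0
            for p in combo:
                e[p] += 1
                w *= a[p]
            c[idx[tuple(e)]] += w
        cq, _ = quad_coeffs(B @ B.T, np.zeros(3), 0.0)
        c[: len(cq)] += cq  # graded basis: the degree<=2 block leads
        U = PolyUnderestimator(n=3, degree=4, coeffs=c, exponents=exps)
        cert = is_sos_convex(U)
        assert cert is not None

    def test_fit_certificates_pass_independent_spot_check(self, rng):
        # Hessian PSD at random points: necessary consequence of the certificate
        P = rng.normal(size=(80, 3))
        f = np.sum(P**2, axis=1) + np.sin(3 * P).sum(axis=1)
        U = fit_underestimator(P, f, degree=4)
        for phi in rng.uniform(-2, 2, size=(100, 3)):
            H = hessian(U, phi)
            lam = np.linalg.eigvalsh(H).min()
            assert lam >= -1e-8 * (1 + np.linalg.norm(H))
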