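"""SOS-convex polynomial underestimation of sampled energies.

Given samples ``(phi_i, f_i)`` of local energy minima in the (typically 3D)
permissive subspace, fit a degree-2d polynomial ``U`` solving

    minimize   sum_i [f_i - U(phi_i)]
    subject to f_i >= U(phi_i)   for all i,
               U is SOS-convex,

so ``U`` is a tight convex envelope of the sampled minima and its global
minimizer approximates the funnel basin.  Verifying convexity of a quartic
is already intractable in general, so convexity is imposed through the
tractable SOS-convexity relaxation: the Hessian quadratic form
``y' H_U(phi) y`` must admit a sum-of-squares representation in ``(phi,
y)``, i.e. a positive semidefinite Gram matrix over the basis
``{phi^gamma y_i : deg gamma <= d-1}``.  Both the fit and the certificate
are semidefinite programs, solved with the in-package barrier solver
(:mod:`ssdu.sdp`).

Numerical conditioning: samples are centered/scaled per coordinate and
energies shifted to minimum zero before the SDP; the returned coefficients
are exactly back-transformed to the caller's coordinates.  A tiny
coefficient-norm ridge (1e-9) breaks ties in underdetermined fits.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sdp import NonNegBlock, PSDBlock, SDPError, solve_sdp

__all__ = [
    "PolyUnderestimator",
    "UnderestimatorError",
    "monomial_basis",
    "fit_underestimator",
    "evaluate",
    "gradient",
    "hessian",
    "minimize_convex",
    "is_sos_convex",
]


class UnderestimatorError(RuntimeError):
    """Fit or minimization failure, carrying solver diagnostics."""


def monomial_basis(n: int, d: int) -> List[Tuple[int, ...]]:
    """All exponent tuples in ``n`` variables with total degree <= ``d``.

    Graded order (degree ascending), lexicographic within a degree; length
    is C(n + d, d).
    """
    if n < 1 or d < 0:
        raise ValueError("need n >= 1 and d >= 0")
    out: List[Tuple[int, ...]] = []
    for deg in range(d + 1):
        block = [e for e in itertools.product(range(deg + 1), repeat=n) if sum(e) == deg]
        block.sort(reverse=True)  # x1-major within each degree
        out.extend(block)
    return out


def _design_matrix(points: np.ndarray, exps: Sequence[Tuple[int, ...]]) -> np.ndarray:
    """Vandermonde-style matrix: entry (i, k) = prod_p points[i, p]**exps[k][p]."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cols = [np.prod(points ** np.asarray(e, dtype=float), axis=1) for e in exps]
    return np.column_stack(cols)


def _affine_pullback(
    coeffs: np.ndarray,
    exps: Sequence[Tuple[int, ...]],
    mu: np.ndarray,
    scale: np.ndarray,
    offset: float,
) -> np.ndarray:
    """Coefficients of ``U((phi - mu)/scale) + offset`` over the same basis."""
    index = {e: k for k, e in enumerate(exps)}
    out = np.zeros(len(exps))
    out[index[tuple([0] * len(mu))]] += offset
    for c, e in zip(coeffs, exps):
        if c == 0.0:
            continue
        pref = c / np.prod(scale ** np.asarray(e, dtype=float))
        ranges = [range(ep + 1) for ep in e]
        for j in itertools.product(*ranges):
            w = pref
            for p, (jp, ep) in enumerate(zip(j, e)):
                w *= math.comb(ep, jp) * (-mu[p]) ** (ep - jp)
            out[index[tuple(j)]] += w
    return out


# ---------------------------------------------------------------------------
# Hessian-form / Gram-matrix structure (cached per (n, d))
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _sos_structure(n: int, d: int):
    """Linear algebra tying degree-2d polynomials to Gram matrices of their
    Hessian forms.

    Gram basis: ``v = (phi^gamma y_i)`` for deg gamma <= d-1, i = 1..n, so
    ``y' H_U(phi) y = v' G v`` for symmetric ``G``.  Returns the poly basis,
    the Gram basis size m, a stack ``H`` with one particular Gram per
    polynomial coefficient (via pseudo-inverse), and an orthonormal stack
    ``N`` of Gram matrices representing the zero polynomial (the freedom the
    SDP optimizes over).
    """
    exps = monomial_basis(n, 2 * d)
    gammas = monomial_basis(n, d - 1)
    gram_basis = [(g, i) for g in gammas for i in range(n)]
    m = len(gram_basis)
    svec_pairs = [(a, b) for a in range(m) for b in range(a, m)]

    def key_of(phi_exp: Tuple[int, ...], i: int, j: int):
        return (tuple(phi_exp), (i, j) if i <= j else (j, i))

    rows: Dict[Tuple, int] = {}

    def row(key) -> int:
        if key not in rows:
            rows[key] = len(rows)
        return rows[key]

    gram_entries = []  # (key, svec index, weight)
    for s_idx, (a, b) in enumerate(svec_pairs):
        (ga, ia), (gb, ib) = gram_basis[a], gram_basis[b]
        prod = tuple(x + y for x, y in zip(ga, gb))
        w = 1.0 if a == b else 2.0
        gram_entries.append((key_of(prod, ia, ib), s_idx, w))

    hess_entries = []  # (key, coeff index, weight)
    for k, alpha in enumerate(exps):
        for p in range(n):
            if alpha[p] >= 2:
                e = list(alpha)
                e[p] -= 2
                hess_entries.append((key_of(tuple(e), p, p), k, alpha[p] * (alpha[p] - 1)))
            for q in range(p + 1, n):
                if alpha[p] >= 1 and alpha[q] >= 1:
                    e = list(alpha)
                    e[p] -= 1
                    e[q] -= 1
                    hess_entries.append((key_of(tuple(e), p, q), k, 2.0 * alpha[p] * alpha[q]))

    for key, _, _ in gram_entries + hess_entries:
        row(key)
    n_rows = len(rows)
    A_gram = np.zeros((n_rows, len(svec_pairs)))
    for key, s_idx, w in gram_entries:
        A_gram[rows[key], s_idx] += w
    A_hess = np.zeros((n_rows, len(exps)))
    for key, k, w in hess_entries:
        A_hess[rows[key], k] += w

    U, S, Vt = np.linalg.svd(A_gram, full_matrices=True)
    rank = int(np.sum(S > 1e-12 * S[0]))
    pinv = Vt[:rank].T @ np.diag(1.0 / S[:rank]) @ U[:, :rank].T
    null_svec = Vt[rank:].T  # (n_svec, M) orthonormal columns

    def unsvec(v: np.ndarray) -> np.ndarray:
        G = np.zeros((m, m))
        for s_idx, (a, b) in enumerate(svec_pairs):
            G[a, b] = v[s_idx]
            G[b, a] = v[s_idx]
        return G

    def svec(G: np.ndarray) -> np.ndarray:
        return np.array([G[a, b] for (a, b) in svec_pairs])

    H_stack = np.stack([unsvec(pinv @ A_hess[:, k]) for k in range(len(exps))])
    N_stack = np.stack([unsvec(null_svec[:, j]) for j in range(null_svec.shape[1])]) if null_svec.shape[1] else np.zeros((0, m, m))
    return {
        "exps": exps,
        "gram_basis": gram_basis,
        "m": m,
        "H": H_stack,
        "N": N_stack,
        "svec": svec,
        "unsvec": unsvec,
        "null_svec": null_svec,
        "pinv": pinv,
        "A_hess": A_hess,
        "A_gram": A_gram,
    }


@dataclass
class PolyUnderestimator:
    """A fitted SOS-convex polynomial underestimator.

    ``coeffs`` are over the full monomial basis (``monomial_basis(n,
    degree)`` order) in the caller's coordinates.  ``sos_certificate``
    carries the PSD Gram matrix of the Hessian form in the preconditioned
    fit coordinates (an affine reparameterization, which preserves
    convexity), its basis, and its smallest eigenvalue.  ``fit_report``
    records per-sample gaps ``f_i - U(phi_i)``, solver status and the
    feasibility tolerance.
    """

    n: int
    degree: int
    coeffs: np.ndarray
    exponents: List[Tuple[int, ...]] = field(repr=False)
    sos_certificate: Optional[dict] = None
    fit_report: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.degree < 2 or self.degree % 2 != 0:
            raise ValueError("degree must be even and >= 2")
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if len(self.coeffs) != len(self.exponents):
            raise ValueError("coefficient/basis length mismatch")

    def __call__(self, phi: np.ndarray) -> np.ndarray:
        return evaluate(self, phi)

    @staticmethod
    def from_coeffs(coeffs: Sequence[float], n: int, degree: int) -> "PolyUnderestimator":
        return PolyUnderestimator(n=n, degree=degree, coeffs=np.asarray(coeffs, float),
                                  exponents=monomial_basis(n, degree))

    def to_dict(self) -> dict:
        """Serializable audit record (coefficients, basis, certificate)."""
        d = {
            "n": self.n,
            "degree": self.degree,
            "exponents": [list(e) for e in self.exponents],
            "coeffs": self.coeffs.tolist(),
        }
        if self.sos_certificate is not None:
            d["sos_certificate"] = {
                "gram": np.asarray(self.sos_certificate["gram"]).tolist(),
                "min_eig": float(self.sos_certificate["min_eig"]),
                "gram_basis": [[list(g), i] for g, i in self.sos_certificate["gram_basis"]],
            }
        if self.fit_report is not None:
            d["fit_report"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                               for k, v in self.fit_report.items()}
        return d


def evaluate(U: PolyUnderestimator, phi: np.ndarray) -> np.ndarray:
    """Exact polynomial evaluation; accepts a point or a stack of points."""
    phi = np.asarray(phi, dtype=float)
    single = phi.ndim == 1
    vals = _design_matrix(np.atleast_2d(phi), U.exponents) @ U.coeffs
    return float(vals[0]) if single else vals


def gradient(U: PolyUnderestimator, phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    g = np.zeros(U.n)
    for c, e in zip(U.coeffs, U.exponents):
        if c == 0.0:
            continue
        for p in range(U.n):
            if e[p] >= 1:
                de = list(e)
                de[p] -= 1
                g[p] += c * e[p] * np.prod(phi ** np.asarray(de, dtype=float))
    return g


def hessian(U: PolyUnderestimator, phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    H = np.zeros((U.n, U.n))
    for c, e in zip(U.coeffs, U.exponents):
        if c == 0.0:
            continue
        for p in range(U.n):
            if e[p] >= 2:
                de = list(e)
                de[p] -= 2
                H[p, p] += c * e[p] * (e[p] - 1) * np.prod(phi ** np.asarray(de, dtype=float))
            for q in range(p + 1, U.n):
                if e[p] >= 1 and e[q] >= 1:
                    de = list(e)
                    de[p] -= 1
                    de[q] -= 1
                    v = c * e[p] * e[q] * np.prod(phi ** np.asarray(de, dtype=float))
                    H[p, q] += v
                    H[q, p] += v
    return H


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _max_margin(G_part: np.ndarray, N_stack: np.ndarray, tol: float = 1e-9):
    """Maximize lambda s.t. G_part + sum_j t_j N_j - lambda I >= 0 (bounded).

    Phase-I search for the best-conditioned Gram representative of a fixed
    Hessian form; lambda* > 0 certifies strict SOS-convexity, lambda* >= 0
    (within tolerance) certifies SOS-convexity.
    """
    m = G_part.shape[0]
    M = N_stack.shape[0]
    scale = 1.0 + float(np.linalg.norm(G_part))
    T, C = 100.0 * scale, scale
    Fs = np.concatenate([N_stack, -np.eye(m)[None]], axis=0) if M else (-np.eye(m)[None])
    blocks = [PSDBlock(F0=G_part, Fs=Fs)]
    # bounds: C - lam >= 0 ; T +- t_j >= 0
    A = np.zeros((1 + 2 * M, M + 1))
    a = np.zeros(1 + 2 * M)
    A[0, M] = -1.0
    a[0] = C
    for j in range(M):
        A[1 + 2 * j, j] = 1.0
        a[1 + 2 * j] = T
        A[2 + 2 * j, j] = -1.0
        a[2 + 2 * j] = T
    blocks.append(NonNegBlock(a=a, A=A))
    lam0 = float(np.linalg.eigvalsh(G_part).min()) - 1.0
    x0 = np.zeros(M + 1)
    x0[M] = lam0
    c = np.zeros(M + 1)
    c[M] = -1.0  # maximize lambda
    res = solve_sdp(c, blocks, x0, Q=None, tol=tol * scale)
    t, lam = res.x[:M], float(res.x[M])
    return t, lam, res


def fit_underestimator(
    points: np.ndarray,
    energies: np.ndarray,
    degree: int = 4,
    tol: float = 1e-6,
    reg: float = 1e-9,
) -> PolyUnderestimator:
    """Fit the tightest SOS-convex degree-``degree`` underestimator.

    ``points`` is (K, n); ``energies`` length K.  Every returned gap
    ``f_i - U(phi_i)`` is >= -tol.  Raises :class:`UnderestimatorError`
    with solver diagnostics on failure.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    energies = np.asarray(energies, dtype=float).ravel()
    K, n = points.shape
    if K == 0:
        raise UnderestimatorError("no sample points")
    if energies.shape != (K,):
        raise UnderestimatorError("points/energies length mismatch")
    if not (np.all(np.isfinite(points)) and np.all(np.isfinite(energies))):
        raise UnderestimatorError("non-finite inputs")
    if degree % 2 != 0 or degree < 2:
        raise ValueError("degree must be even and >= 2")
    d = degree // 2
    struct = _sos_structure(n, d)
    exps = struct["exps"]
    N_coef = len(exps)
    if K < N_coef:
        warnings.warn(
            f"underdetermined fit: K={K} samples for {N_coef} coefficients; "
            "ridge tie-breaking keeps the solution unique",
            stacklevel=2,
        )

    # precondition: center/scale points; shift energies to min 0 and scale
    # to unit spread (exactly undone on output)
    mu = points.mean(axis=0)
    sc = points.std(axis=0)
    sc[sc < 1e-12] = 1.0
    P = (points - mu) / sc
    f0 = float(energies.min())
    f_scale = float(energies.std())
    if f_scale < 1e-12:
        f_scale = 1.0
    f = (energies - f0) / f_scale

    Phi = _design_matrix(P, exps)
    H_stack, N_stack = struct["H"], struct["N"]
    M = N_stack.shape[0]
    nvar = N_coef + M

    # strictly feasible start: U0 = -1 + delta * sum_{j=1..d} ||u||^(2j),
    # whose Hessian form has an explicit positive definite Gram for d <= 2
    # and a phase-I-found one otherwise.
    norms2 = np.sum(P**2, axis=1)
    B = float(sum((norms2 ** j).max() for j in range(1, d + 1)))
    delta = 0.5 / (1.0 + B)
    c0 = np.zeros(N_coef)
    idx = {e: k for k, e in enumerate(exps)}
    c0[idx[tuple([0] * n)]] = -1.0
    # coefficients of delta * sum_j (sum_p u_p^2)^j
    for j in range(1, d + 1):
        for combo in itertools.combinations_with_replacement(range(n), j):
            e = [0] * n
            for p in combo:
                e[p] += 2
            count = math.factorial(j)
            for rep in set(combo):
                count //= math.factorial(combo.count(rep))
            c0[idx[tuple(e)]] += delta * count
    G_part0 = np.tensordot(c0, H_stack, axes=(0, 0))
    if M:
        t0, lam, _ = _max_margin(G_part0, N_stack, tol=1e-7)
    else:
        t0, lam = np.zeros(0), float(np.linalg.eigvalsh(G_part0).min())
    if lam <= 0:
        raise UnderestimatorError(
            f"could not construct a strictly feasible start (margin {lam:.3e})"
        )
    x0 = np.concatenate([c0, t0])

    # SDP: minimize -(sum_i Phi_i) c + reg ||x||^2
    c_obj = np.zeros(nvar)
    c_obj[:N_coef] = -Phi.sum(axis=0)
    Q = 2.0 * reg * np.eye(nvar)
    Fs = np.concatenate([H_stack, N_stack], axis=0)
    psd = PSDBlock(F0=np.zeros((struct["m"],) * 2), Fs=Fs)
    A_ineq = np.zeros((K, nvar))
    A_ineq[:, :N_coef] = -Phi
    ineq = NonNegBlock(a=f, A=A_ineq)
    try:
        res = solve_sdp(c_obj, [psd, ineq], x0, Q=Q, tol=1e-9 * (1.0 + abs(float(f.max()))))
    except SDPError as exc:
        raise UnderestimatorError(f"SDP solve failed: {exc}") from exc

    c_norm, t_opt = res.x[:N_coef], res.x[N_coef:]
    G = np.tensordot(c_norm, H_stack, axes=(0, 0))
    if M:
        G = G + np.tensordot(t_opt, N_stack, axes=(0, 0))
    coeffs = _affine_pullback(f_scale * c_norm, exps, mu, sc, offset=f0)
    U = PolyUnderestimator(n=n, degree=degree, coeffs=coeffs, exponents=exps)
    gaps = energies - evaluate(U, points)
    U.sos_certificate = {
        "gram": G,
        "gram_basis": struct["gram_basis"],
        "min_eig": float(np.linalg.eigvalsh(G).min()),
        "coords": {"mu": mu, "scale": sc},
    }
    U.fit_report = {
        "gaps": gaps,
        "total_gap": float(gaps.sum()),
        "min_gap": float(gaps.min()),
        "tol": tol,
        "solver_gap_bound": res.gap_bound,
        "newton_steps": res.newton_steps,
        "K": K,
    }
    if gaps.min() < -tol:
        raise UnderestimatorError(
            f"fit violates underestimation: min gap {gaps.min():.3e} < -{tol}"
        )
    return U


def minimize_convex(
    U: PolyUnderestimator,
    init: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> Tuple[np.ndarray, float]:
    """Global minimizer of a certified-convex polynomial by damped Newton.

    Convexity makes any stationary point global; the result is independent
    of ``init`` up to the gradient tolerance.  Raises on unbounded-below
    polynomials (possible for degenerate fits whose quadratic part vanishes
    along some direction).
    """
    x = np.zeros(U.n) if init is None else np.asarray(init, dtype=float).copy()
    scale0 = 1.0 + float(np.linalg.norm(x))
    for _ in range(max_iter):
        g = gradient(U, x)
        if np.linalg.norm(g) <= tol:
            return x, float(evaluate(U, x))
        H = hessian(U, x)
        ridge = 1e-10 * (1.0 + abs(np.trace(H)) / U.n)
        try:
            step = np.linalg.solve(H + ridge * np.eye(U.n), -g)
        except np.linalg.LinAlgError:
            step = -g
        if float(g @ step) >= 0:  # not a descent direction (flat Hessian)
            step = -g
        f_cur = float(evaluate(U, x))
        alpha, ok = 1.0, False
        for _ls in range(80):
            xn = x + alpha * step
            if float(evaluate(U, xn)) < f_cur - 1e-4 * alpha * abs(float(g @ step)):
                ok = True
                break
            alpha *= 0.5
        if not ok:
            break
        x = xn
        if np.linalg.norm(x) > 1e8 * scale0 or float(evaluate(U, x)) < -1e14:
            raise UnderestimatorError("polynomial appears unbounded below")
    g = gradient(U, x)
    if np.linalg.norm(g) > max(tol, 1e-6 * (1.0 + abs(float(evaluate(U, x))))):
        raise UnderestimatorError(
            f"Newton failed to reach stationarity (|grad| = {np.linalg.norm(g):.3e}); "
            "the polynomial may be unbounded below"
        )
    return x, float(evaluate(U, x))


def is_sos_convex(U: PolyUnderestimator, tol: float = 1e-7) -> Optional[dict]:
    """Attempt an SOS certificate for the Hessian form of ``U``.

    Returns a certificate dict (PSD Gram matrix, its basis, the achieved
    margin) on success and ``None`` when the feasibility SDP shows no PSD
    Gram exists within tolerance.  Solver failures raise.
    """
    d = U.degree // 2
    struct = _sos_structure(U.n, d)
    G_part = np.tensordot(U.coeffs, struct["H"], axes=(0, 0))
    N_stack = struct["N"]
    if N_stack.shape[0] == 0:
        lam = float(np.linalg.eigvalsh(G_part).min())
        G, t = G_part, np.zeros(0)
    else:
        t, lam, _ = _max_margin(G_part, N_stack)
        G = G_part + np.tensordot(t, N_stack, axes=(0, 0))
    scale = 1.0 + float(np.linalg.norm(G_part))
    if lam < -tol * scale:
        return None
    return {"gram": G, "gram_basis": struct["gram_basis"], "min_eig": float(np.linalg.eigvalsh(G).min()), "margin": lam}
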