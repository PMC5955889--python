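"""A small dense interior-point solver for linear matrix inequalities.

Solves problems of the form

    minimize    c'x + (1/2) x'Qx          (Q PSD, typically a tiny ridge)
    subject to  F0_b + sum_k x_k Fk_b  >= 0   (PSD, for each matrix block b)
                a_b  + A_b x           >= 0   (elementwise, vector blocks)

by the classic log-det barrier path-following method: for an increasing
sequence of barrier weights t, minimize

    t (c'x + x'Qx/2) - sum_b log det S_b(x) - sum_i log s_i(x)

by damped Newton from a strictly feasible iterate.  On exit the objective
is within nu/t of optimal, where nu is the total barrier parameter (sum of
block orders).

The SOS-convex underestimation problems this package generates are tiny
(PSD blocks of order <= 30, under ~150 scalar variables), which a dense
textbook implementation handles quickly and to high accuracy.  Callers must
supply a strictly feasible starting point; the phase-I construction for the
underestimator lives in :mod:`ssdu.underestimator`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["PSDBlock", "NonNegBlock", "SDPResult", "SDPError", "solve_sdp"]


class SDPError(RuntimeError):
    """Raised when the barrier solver cannot make progress."""


@dataclass
class PSDBlock:
    """Constraint ``F0 + sum_k x_k Fs[k] >= 0`` (matrix PSD)."""

    F0: np.ndarray          # (m, m) symmetric
    Fs: np.ndarray          # (nvar, m, m) symmetric stack

    def __post_init__(self) -> None:
        self.F0 = np.asarray(self.F0, dtype=float)
        self.Fs = np.asarray(self.Fs, dtype=float)
        m = self.F0.shape[0]
        if self.F0.shape != (m, m) or self.Fs.ndim != 3 or self.Fs.shape[1:] != (m, m):
            raise ValueError("inconsistent PSD block shapes")

    @property
    def order(self) -> int:
        return self.F0.shape[0]

    def matrix(self, x: np.ndarray) -> np.ndarray:
        return self.F0 + np.tensordot(x, self.Fs, axes=(0, 0))


@dataclass
class NonNegBlock:
    """Constraint ``a + A x >= 0`` (elementwise)."""

    a: np.ndarray           # (m,)
    A: np.ndarray           # (m, nvar)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape[0] != self.a.shape[0]:
            raise ValueError("inconsistent non-negativity block shapes")

    @property
    def order(self) -> int:
        return self.a.shape[0]

    def slack(self, x: np.ndarray) -> np.ndarray:
        return self.a + self.A @ x


Block = Union[PSDBlock, NonNegBlock]


@dataclass
class SDPResult:
    x: np.ndarray
    objective: float
    gap_bound: float        # nu / t at exit: certified suboptimality of `objective`
    barrier_stages: int
    newton_steps: int


def _min_slack(blocks: Sequence[Block], x: np.ndarray) -> float:
    """Smallest eigenvalue / slack over all blocks (strictly > 0 iff interior)."""
    worst = np.inf
    for b in blocks:
        if isinstance(b, PSDBlock):
            worst = min(worst, float(np.linalg.eigvalsh(b.matrix(x)).min()))
        else:
            worst = min(worst, float(b.slack(x).min()))
    return worst


def _is_interior(blocks: Sequence[Block], x: np.ndarray) -> bool:
    for b in blocks:
        if isinstance(b, PSDBlock):
            try:
                np.linalg.cholesky(b.matrix(x))
            except np.linalg.LinAlgError:
                return False
        else:
            if np.any(b.slack(x) <= 0):
                return False
    return True


def _barrier_grad_hess(blocks: Sequence[Block], x: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    nvar = x.shape[0]
    val = 0.0
    grad = np.zeros(nvar)
    hess = np.zeros((nvar, nvar))
    for b in blocks:
        if isinstance(b, PSDBlock):
            S = b.matrix(x)
            try:
                cf = cho_factor(S, lower=True)
            except np.linalg.LinAlgError as exc:
                raise SDPError("iterate left the interior of the PSD cone") from exc
            val -= 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            # M_k = S^{-1} F_k ; grad_k = -tr(M_k) ; H_jk = tr(M_j M_k)
            M = np.stack([cho_solve(cf, F) for F in b.Fs])
            grad -= np.einsum("kii->k", M)
            H = np.einsum("jab,kba->jk", M, M)
            hess += 0.5 * (H + H.T)
        else:
            s = b.slack(x)
            if np.any(s <= 0):
                raise SDPError("iterate left the interior of the linear constraints")
            val -= float(np.sum(np.log(s)))
            inv = 1.0 / s
            grad -= b.A.T @ inv
            hess += (b.A * (inv**2)[:, None]).T @ b.A
    return val, grad, hess


def solve_sdp(
    c: np.ndarray,
    blocks: Sequence[Block],
    x0: np.ndarray,
    Q: Optional[np.ndarray] = None,
    tol: float = 1e-9,
    mu: float = 20.0,
    t0: float = 1.0,
    newton_tol: float = 1e-11,
    max_newton: int = 200,
) -> SDPResult:
    """Path-following barrier solve from a strictly feasible ``x0``.

    Returns an ``SDPResult`` whose ``gap_bound`` certifies the objective is
    within that amount of the true optimum (standard nu/t bound).
    """
    c = np.asarray(c, dtype=float)
    x = np.asarray(x0, dtype=float).copy()
    nvar = x.shape[0]
    if c.shape != (nvar,):
        raise ValueError("objective/variable dimension mismatch")
    if _min_slack(blocks, x) <= 0:
        raise SDPError("starting point is not strictly feasible")
    if Q is not None:
        Q = np.asarray(Q, dtype=float)

    def obj(xv: np.ndarray) -> float:
        v = float(c @ xv)
        if Q is not None:
            v += 0.5 * float(xv @ Q @ xv)
        return v

    nu = float(sum(b.order for b in blocks))
    t = float(t0)
    stages = 0
    newton_total = 0
    while True:
        stages += 1
        # Damped Newton on the self-concordant function t*obj + barrier.
        # The Newton decrement lambda is affine-invariant, so the step rule
        # alpha = 1/(1+lambda) (lambda large) / full step (lambda small)
        # needs no merit-function comparisons -- important because the
        # merit value grows like t and would drown small decrements in
        # floating-point noise.
        for _ in range(max_newton):
            _, bgrad, bhess = _barrier_grad_hess(blocks, x)
            g = t * c + bgrad
            H = bhess.copy()
            if Q is not None:
                g = g + t * (Q @ x)
                H = H + t * Q
            # Jacobi-scaled solve for conditioning
            dscale = 1.0 / np.sqrt(np.maximum(np.diag(H), 1e-300))
            Hs = H * dscale[:, None] * dscale[None, :]
            gs = g * dscale
            ridge = 0.0
            for _try in range(8):
                try:
                    Hs2 = Hs + ridge * np.eye(nvar) if ridge else Hs
                    cf = cho_factor(Hs2)
                    ds = -cho_solve(cf, gs)
                    break
                except np.linalg.LinAlgError:
                    ridge = max(1e-12, ridge * 100.0)
            else:
                ds = -np.linalg.lstsq(Hs, gs, rcond=None)[0]
            d = ds * dscale
            lam2 = max(-float(g @ d), 0.0)
            if lam2 <= newton_tol:
                break
            lam = np.sqrt(lam2)
            alpha = 1.0 if lam < 0.25 else 1.0 / (1.0 + lam)
            for _ls in range(60):
                if _is_interior(blocks, x + alpha * d):
                    break
                alpha *= 0.5
            else:
                break
            x = x + alpha * d
            newton_total += 1
        if nu / t < tol:
            break
        t *= mu
        if t > 1e18:
            break
    return SDPResult(x=x, objective=obj(x), gap_bound=nu / t, barrier_stages=stages, newton_steps=newton_total)
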