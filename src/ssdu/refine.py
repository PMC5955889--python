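"""The SSDU refinement loop.

Each iteration: (1) DBSCAN on the 5D reduced coordinates splits the
ensemble into dense sub-clusters (one per putative energy funnel) and
discards outliers; (2) per cluster, a PCA basis is fitted, the lowest-energy
fraction eta of members is locally minimized and used to fit an SOS-convex
polynomial underestimator in the 3D permissive subspace; the underestimator
minimum, completed with the cluster-mean restrictive coordinates and
center-to-center distance, seeds k_bar uniformly perturbed samples that are
locally minimized; (3) all new conformations are merged with the current
ensemble and the K lowest-energy ones are retained.  The loop stops after
``max_iter`` iterations (default 3) or when the best energy improves by
less than ``rel_tol`` relative.

Randomness: a single top-level seed; each (iteration, cluster) pair derives
its own child seed as ``SeedSequence(seed, spawn_key=(iteration, cluster))``
so the output is reproducible independently of cluster enumeration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .geometry import Conformation, attach_r
from .landscape import EnergyModel
from .subspace import PCABasis, fit_pca, from_principal, permissive, to_principal
from .underestimator import (
    UnderestimatorError,
    fit_underestimator,
    minimize_convex,
)

__all__ = [
    "SSDUParams",
    "ClusterAssignment",
    "LocalMinOpts",
    "dbscan",
    "select_fit_set",
    "local_minimize",
    "sample_around",
    "reconstruct",
    "ssdu_refine",
]


@dataclass
class SSDUParams:
    """Tunable parameters of the refinement loop.

    Defaults follow the published protocol where stated: DBSCAN radius
    ``eps = 1.0`` with minimum cluster population ``n_min = 100``, fit-set
    fraction ``eta = 0.3``, three iterations, and ``k_bar`` (samples per
    cluster per iteration) equal to the ensemble size K.  ``beta`` scales
    the uniform resampling range ``(-0.5 beta sigma_i, 0.5 beta sigma_i)``
    per principal coordinate.
    """

    K: Optional[int] = None
    eps: float = 1.0
    n_min: int = 100
    eta: float = 0.3
    beta: float = 2.0
    k_bar: Optional[int] = None
    max_iter: int = 3
    degree: int = 4
    seed: int = 0
    rel_tol: float = 1e-4
    n_permissive: int = 3
    include_r_in_clustering: bool = False
    local_opts: "LocalMinOpts" = field(default_factory=lambda: LocalMinOpts())

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must be in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.K is not None and self.K < self.n_min:
            raise ValueError("ensemble size K must be >= n_min")


@dataclass
class LocalMinOpts:
    """Rigid-body local minimizer settings (finite-difference quasi-Newton)."""

    tol: float = 1e-7
    maxiter: int = 80


@dataclass
class ClusterAssignment:
    """DBSCAN labels: -1 = outlier, 0..n_clusters-1 = cluster ids."""

    labels: np.ndarray
    n_clusters: int

    @property
    def sizes(self) -> np.ndarray:
        return np.array([(self.labels == c).sum() for c in range(self.n_clusters)])

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def dbscan(X: np.ndarray, eps: float, n_min: int) -> ClusterAssignment:
    """Density-based clustering with a fixed deterministic border rule.

    Standard DBSCAN semantics (Euclidean metric): a core point has at least
    ``n_min`` neighbors within ``eps`` (itself included); clusters are the
    maximal density-connected sets of core points plus the border points
    they reach; everything else is labeled -1.  Border points join the
    cluster of the first core point (in input scan order) that reaches
    them, making the partition independent of hidden iteration state.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty input")
    D = cdist(X, X)
    neigh = [np.flatnonzero(D[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= n_min for nb in neigh])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cluster
        queue = [i]
        while queue:
            j = queue.pop(0)
            for k in neigh[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        queue.append(k)
        cluster += 1
    return ClusterAssignment(labels=labels, n_clusters=cluster)


def select_fit_set(energies: np.ndarray, eta: float) -> np.ndarray:
    """Indices of the ``ceil(eta * size)`` lowest-energy members (stable ties)."""
    energies = np.asarray(energies, dtype=float)
    if energies.size == 0:
        raise ValueError("empty cluster")
    m = int(np.ceil(eta * energies.size))
    return np.argsort(energies, kind="stable")[:m]


def local_minimize(
    model: EnergyModel,
    psi: Conformation,
    opts: Optional[LocalMinOpts] = None,
) -> Conformation:
    """Rigid-body local minimization of the 6D placement.

    L-BFGS-B with finite-difference gradients and an ``r > 0`` bound; the
    result never has higher energy than the input (the input is kept if the
    line search cannot improve on it).  Deterministic.
    """
    opts = opts or LocalMinOpts()
    psi0 = psi.psi if isinstance(psi, Conformation) else np.asarray(psi, float)
    f0 = model(psi0)
    if not np.isfinite(f0):
        raise ValueError("energy is not finite at the starting conformation")

    def f(p: np.ndarray) -> float:
        return model(p)

    bounds = [(1e-3, None)] + [(None, None)] * 5
    res = minimize(f, psi0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": opts.maxiter, "gtol": opts.tol, "ftol": 1e-14})
    if np.isfinite(res.fun) and res.fun <= f0:
        return Conformation.from_psi(res.x, energy=float(res.fun))
    return Conformation.from_psi(psi0, energy=float(f0))


def sample_around(
    basis: PCABasis,
    phi_star: np.ndarray,
    Z: np.ndarray,
    beta: float,
    k_bar: int,
    seed: int,
) -> np.ndarray:
    """Uniform resampling around the underestimator minimum, in x-space.

    ``z* = (phi*, mean z4, mean z5)`` completes the permissive minimizer
    with the cluster-mean restrictive coordinates; each of the ``k_bar``
    samples perturbs ``z*`` by independent uniforms in
    ``(-0.5 beta sigma_i, 0.5 beta sigma_i)`` and is mapped back through
    ``x = W(z* + s) + xbar``.
    """
    if k_bar < 1:
        raise ValueError("k_bar must be >= 1")
    phi_star = np.asarray(phi_star, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n_perm = phi_star.shape[0]
    z_star = np.concatenate([phi_star, Z[:, n_perm:].mean(axis=0)])
    rng = np.random.default_rng(seed)
    half = 0.5 * beta * basis.sigma
    S = rng.uniform(-half, half, size=(k_bar, basis.dim))
    return from_principal(basis, z_star + S)


def reconstruct(X_tilde: np.ndarray, r_bar: float) -> List[Conformation]:
    """Append the cluster-mean center-to-center distance to each x-sample."""
    if r_bar <= 0:
        raise ValueError("r_bar must be positive")
    X_tilde = np.atleast_2d(np.asarray(X_tilde, dtype=float))
    return [attach_r(x, r_bar) for x in X_tilde]


def _child_seed(seed: int, iteration: int, cluster: int) -> int:
    """Documented counter scheme: SeedSequence(seed, spawn_key=(it, cluster))."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(iteration, cluster))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def ssdu_refine(
    model: EnergyModel,
    ensemble: Sequence[Conformation],
    params: SSDUParams,
    full_output: bool = False,
):
    """Run the SSDU loop; returns the refined ensemble (size K, lowest energies).

    With ``full_output`` also returns a run log (per-iteration cluster
    counts, best energies, underestimator gap summaries).  The best and
    k-th best energies never increase across iterations because the input
    is always part of the merge pool.
    """
    ensemble = list(ensemble)
    K = params.K if params.K is not None else len(ensemble)
    if len(ensemble) != K:
        raise ValueError(f"ensemble size {len(ensemble)} != params.K = {K}")
    current = [c if c.energy is not None else c.with_energy(model(c)) for c in ensemble]
    log: dict = {"iterations": [], "params_seed": params.seed}
    best_prev = min(c.energy for c in current)
    k_bar = params.k_bar if params.k_bar is not None else K

    for it in range(1, params.max_iter + 1):
        coords = np.array([c.psi if params.include_r_in_clustering else c.x for c in current])
        assign = dbscan(coords, params.eps, params.n_min)
        it_log = {"iteration": it, "n_clusters": assign.n_clusters, "clusters": []}
        if assign.n_clusters == 0:
            warnings.warn("DBSCAN found no clusters (all outliers); ensemble returned unchanged")
            log["iterations"].append(it_log)
            break
        X = np.array([c.x for c in current])
        energies = np.array([c.energy for c in current])
        new_confs: List[Conformation] = []
        for cid in range(assign.n_clusters):
            idx = assign.members(cid)
            basis = fit_pca(X[idx])
            fit_local = select_fit_set(energies[idx], params.eta)
            fit_idx = idx[fit_local]
            minimized = [local_minimize(model, current[i], params.local_opts) for i in fit_idx]
            Xmin = np.array([c.x for c in minimized])
            fmin = np.array([c.energy for c in minimized])
            Phi = permissive(to_principal(basis, Xmin), params.n_permissive)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # underdetermined-fit warnings
                    U = fit_underestimator(Phi, fmin, degree=params.degree)
                phi_star, u_star = minimize_convex(U, init=Phi[int(np.argmin(fmin))])
            except UnderestimatorError as exc:
                warnings.warn(f"cluster {cid}: underestimation failed ({exc}); cluster skipped")
                continue
            Z = to_principal(basis, X[idx])
            seed_c = _child_seed(params.seed, it, cid)
            X_new = sample_around(basis, phi_star, Z, params.beta, k_bar, seed_c)
            r_bar = float(np.mean([current[i].r for i in idx]))
            candidates = reconstruct(X_new, r_bar)
            new_confs.extend(local_minimize(model, c, params.local_opts) for c in candidates)
            it_log["clusters"].append({
                "cluster": cid,
                "size": int(idx.size),
                "fit_set": int(fit_idx.size),
                "total_gap": float(U.fit_report["total_gap"]),
                "phi_star": np.asarray(phi_star).tolist(),
                "u_star": float(u_star),
            })
        pool = current + new_confs
        pool_e = np.array([c.energy for c in pool])
        keep = np.argsort(pool_e, kind="stable")[:K]
        current = [pool[i] for i in keep]
        best = float(min(c.energy for c in current))
        it_log["best_energy"] = best
        log["iterations"].append(it_log)
        improvement = (best_prev - best) / max(abs(best_prev), 1e-12)
        if it_log["clusters"] and improvement < params.rel_tol and it < params.max_iter:
            best_prev = best
            break
        best_prev = best
    if full_output:
        return current, log
    return current
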