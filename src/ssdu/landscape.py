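"""Energy models: synthetic multi-funnel landscapes and a toy rigid-body physics.

The synthetic landscape emulates the structure of a docking-refinement
input: one or more anisotropic funnels in the 5D reduced coordinate space,
each steep along two "restrictive" eigendirections and smooth along three
"permissive" ones, a stiff quadratic well in the center-to-center distance
``r``, and a deterministic high-frequency sinusoidal ruggedness standing in
for the many superimposed local minima of a real binding-energy surface.
The decoy generator draws Boltzmann-like per-funnel Gaussian clouds plus
uniform outliers, mimicking the low-energy output of FFT-based global
sampling.

The toy rigid-body model is a Lennard-Jones + Coulomb pairwise sum over two
point sets, implementing the force-field subset of the weighted-sum energy
contract (knowledge-based terms need external parameter databases and are
deliberately not modeled; the weights type rejects them so a
misconfiguration fails loudly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .geometry import Conformation, RigidBody, place_ligand

__all__ = [
    "EnergyModel",
    "Funnel",
    "FunnelSpec",
    "EnergyWeights",
    "FunnelEnergyModel",
    "make_funnel_landscape",
    "ground_truth",
    "generate_decoy_ensemble",
    "ToyRigidEnergyModel",
    "toy_rigid_energy",
    "default_funnel_spec",
]

COULOMB_KCAL = 332.0636  # kcal/mol * Angstrom / e^2


class EnergyModel:
    """Deterministic scalar energy ``f(psi)`` over 6D conformations.

    Implementations provide :meth:`energy`; evaluation is bit-reproducible
    (same input, same output).  ``__call__`` accepts a :class:`Conformation`
    or a length-6 array; :meth:`energy_many` a stack of psi rows.
    """

    def energy(self, psi: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def energy_many(self, Psi: np.ndarray) -> np.ndarray:
        Psi = np.atleast_2d(np.asarray(Psi, dtype=float))
        return np.array([self.energy(p) for p in Psi])

    def __call__(self, psi: Union[Conformation, np.ndarray]) -> float:
        if isinstance(psi, Conformation):
            psi = psi.psi
        psi = np.asarray(psi, dtype=float)
        if psi.shape != (6,):
            raise ValueError(f"psi must be a 6-vector, got shape {psi.shape}")
        if not np.all(np.isfinite(psi)):
            raise ValueError("psi must be finite")
        return float(self.energy(psi))


@dataclass
class Funnel:
    """One quadratic funnel in the reduced 5D space plus an ``r`` well.

    ``curvature`` is the 5x5 SPD matrix A (steep eigenvalues = restrictive
    directions, small ones = permissive); ``depth`` the energy at the basin
    bottom; ``r_ref`` the preferred center-to-center distance (Angstrom).
    """

    center: np.ndarray
    r_ref: float
    depth: float
    curvature: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.curvature = np.asarray(self.curvature, dtype=float)
        if self.center.shape != (5,) or self.curvature.shape != (5, 5):
            raise ValueError("funnel center must be 5D with a 5x5 curvature")
        if not np.allclose(self.curvature, self.curvature.T, atol=1e-10):
            raise ValueError("curvature must be symmetric")
        if np.linalg.eigvalsh(self.curvature).min() <= 0:
            raise ValueError("curvature must be positive definite")
        if self.r_ref <= 0:
            raise ValueError("r_ref must be positive")


@dataclass
class FunnelSpec:
    """Full synthetic-landscape specification (funnels + ruggedness + outliers)."""

    funnels: List[Funnel]
    k_r: float = 50.0
    rho_rug: float = 0.0
    omega: np.ndarray = field(default_factory=lambda: np.array([8.0, 9.0, 10.0, 11.0, 12.0]))
    p_out: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.funnels:
            raise ValueError("at least one funnel is required")
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (5,):
            raise ValueError("omega must be a 5-vector")
        if not 0.0 <= self.p_out < 1.0:
            raise ValueError("p_out must be in [0, 1)")
        if self.k_r <= 0:
            raise ValueError("k_r must be positive")
        if self.rho_rug < 0:
            raise ValueError("rho_rug must be non-negative")

    def to_dict(self) -> dict:
        return {
            "funnels": [
                {
                    "center": f.center.tolist(),
                    "r_ref": f.r_ref,
                    "depth": f.depth,
                    "curvature": f.curvature.tolist(),
                }
                for f in self.funnels
            ],
            "k_r": self.k_r,
            "rho_rug": self.rho_rug,
            "omega": self.omega.tolist(),
            "p_out": self.p_out,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "FunnelSpec":
        funnels = [
            Funnel(
                center=np.asarray(f["center"], float),
                r_ref=float(f["r_ref"]),
                depth=float(f["depth"]),
                curvature=np.asarray(f["curvature"], float),
            )
            for f in d["funnels"]
        ]
        return FunnelSpec(
            funnels=funnels,
            k_r=float(d.get("k_r", 50.0)),
            rho_rug=float(d.get("rho_rug", 0.0)),
            omega=np.asarray(d.get("omega", [8.0, 9.0, 10.0, 11.0, 12.0]), float),
            p_out=float(d.get("p_out", 0.0)),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class EnergyWeights:
    """Weights of the implemented force-field terms of the weighted-sum energy.

    Only the Lennard-Jones (``w_vdw``) and Coulomb (``w_coul``) terms are
    modeled; the knowledge-based terms of the full docking potential need
    external parameterizations and are rejected here rather than silently
    ignored.
    """

    w_vdw: float = 1.0
    w_coul: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w_vdw) and np.isfinite(self.w_coul)):
            raise ValueError("weights must be finite")

    @staticmethod
    def from_dict(d: dict) -> "EnergyWeights":
        known = {"w_vdw", "w_coul"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unsupported energy terms {sorted(unknown)}: only the "
                f"Lennard-Jones and Coulomb terms are implemented"
            )
        return EnergyWeights(**{k: float(v) for k, v in d.items()})


class FunnelEnergyModel(EnergyModel):
    """min-of-quadratics multi-funnel landscape with sinusoidal ruggedness.

    ``f(psi) = min_j [d_j + (x - c_j)' A_j (x - c_j) + k_r (r - r_j)^2]
               + rho_rug * sum_i sin(omega_i x_i + phase_i)``

    with the five phases drawn once from the spec seed, so the model is a
    fixed deterministic function.
    """

    def __init__(self, spec: FunnelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.phases = rng.uniform(0.0, 2.0 * np.pi, size=5)
        self._ground_truth: Optional[Tuple[Conformation, float]] = None

    def energy(self, psi: np.ndarray) -> float:
        return float(self.energy_many(psi[None, :])[0])

    def energy_many(self, Psi: np.ndarray) -> np.ndarray:
        Psi = np.atleast_2d(np.asarray(Psi, dtype=float))
        r, X = Psi[:, 0], Psi[:, 1:]
        best = np.full(Psi.shape[0], np.inf)
        for f in self.spec.funnels:
            dx = X - f.center
            quad = f.depth + np.einsum("ij,jk,ik->i", dx, f.curvature, dx)
            quad = quad + self.spec.k_r * (r - f.r_ref) ** 2
            best = np.minimum(best, quad)
        if self.spec.rho_rug > 0:
            best = best + self.spec.rho_rug * np.sin(
                X * self.spec.omega + self.phases
            ).sum(axis=1)
        return best

    def ground_truth(self) -> Tuple[Conformation, float]:
        """Location/value of the global minimum (cached; see :func:`ground_truth`)."""
        if self._ground_truth is None:
            self._ground_truth = ground_truth(self.spec, model=self)
        return self._ground_truth


def make_funnel_landscape(spec: Union[FunnelSpec, Sequence[Funnel]]) -> FunnelEnergyModel:
    """Build the deterministic synthetic landscape from its specification."""
    if not isinstance(spec, FunnelSpec):
        spec = FunnelSpec(funnels=list(spec))
    return FunnelEnergyModel(spec)


def ground_truth(
    spec: FunnelSpec,
    model: Optional[FunnelEnergyModel] = None,
    n_starts_per_funnel: int = 60,
) -> Tuple[Conformation, float]:
    """Global minimum by multi-start local minimization plus refinement.

    Starts at every funnel center and at seeded Gaussian perturbations of
    each center (covariance ``A_j^{-1}``, wide enough to hop between
    ruggedness wells); the best local minimum is returned.  With zero
    ruggedness this is exactly the lowest funnel bottom.
    """
    if model is None:
        model = make_funnel_landscape(spec)

    def f6(psi: np.ndarray) -> float:
        return float(model.energy_many(psi[None, :])[0])

    rng = np.random.default_rng(spec.seed + 1)
    starts = []
    for fn in spec.funnels:
        center6 = np.concatenate([[fn.r_ref], fn.center])
        starts.append(center6)
        if spec.rho_rug > 0:
            cov = np.linalg.inv(fn.curvature)
            L = np.linalg.cholesky(cov)
            for _ in range(n_starts_per_funnel):
                x = fn.center + L @ rng.normal(size=5)
                starts.append(np.concatenate([[fn.r_ref], x]))
    best_psi, best_e = None, np.inf
    for s in starts:
        res = minimize(f6, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        res = minimize(f6, res.x, method="Powell",
                       options={"xtol": 1e-12, "ftol": 1e-14})
        if res.fun < best_e and res.x[0] > 0:
            best_psi, best_e = res.x, float(res.fun)
    return Conformation.from_psi(best_psi, energy=best_e), best_e


def _funnel_weights(spec: FunnelSpec, temperature: float) -> np.ndarray:
    """Boltzmann-like per-funnel occupancies exp(-d_j / T), normalized."""
    d = np.array([f.depth for f in spec.funnels])
    w = np.exp(-(d - d.min()) / max(temperature, 1e-12))
    return w / w.sum()


def generate_decoy_ensemble(
    model: FunnelEnergyModel,
    spec: FunnelSpec,
    K: int,
    temperature: float = 1.0,
    seed: int = 0,
    return_labels: bool = False,
):
    """Draw a PIPER-like decoy ensemble of exactly ``K`` conformations.

    ``round(p_out * K)`` uniform outliers in the funnel bounding box; the
    rest split across funnels proportionally to Boltzmann weights and drawn
    as Gaussians around each center with covariance ``temperature *
    A_j^{-1}`` (and ``r`` jitter with variance ``temperature / (2 k_r)``).
    Every conformation carries its model energy.  With ``return_labels``
    also returns the provenance of each row (funnel index, -1 = outlier).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    n_out = int(round(spec.p_out * K))
    n_fun = K - n_out
    weights = _funnel_weights(spec, temperature)
    counts = np.floor(weights * n_fun).astype(int)
    # largest-remainder allocation of the leftover samples (deterministic)
    rem = weights * n_fun - counts
    for j in np.argsort(-rem)[: n_fun - counts.sum()]:
        counts[j] += 1

    rows, labels = [], []
    for j, (fn, cnt) in enumerate(zip(spec.funnels, counts)):
        if cnt == 0:
            continue
        L = np.linalg.cholesky(temperature * np.linalg.inv(fn.curvature))
        X = fn.center + rng.normal(size=(cnt, 5)) @ L.T
        r = fn.r_ref + rng.normal(scale=np.sqrt(temperature / (2.0 * spec.k_r)), size=cnt)
        r = np.maximum(r, 1e-3)
        rows.append(np.column_stack([r, X]))
        labels.extend([j] * cnt)
    if n_out:
        lo, hi = _bounding_box(spec, temperature)
        X = rng.uniform(lo[1:], hi[1:], size=(n_out, 5))
        r = rng.uniform(lo[0], hi[0], size=n_out)
        rows.append(np.column_stack([r, X]))
        labels.extend([-1] * n_out)
    Psi = np.vstack(rows)
    energies = model.energy_many(Psi)
    ensemble = [Conformation.from_psi(p, energy=e) for p, e in zip(Psi, energies)]
    if return_labels:
        return ensemble, np.asarray(labels)
    return ensemble


def _bounding_box(spec: FunnelSpec, temperature: float) -> Tuple[np.ndarray, np.ndarray]:
    """Box containing the funnel clouds with a generous margin (for outliers)."""
    centers = np.array([f.center for f in spec.funnels])
    spreads = np.array([
        np.sqrt(temperature * np.linalg.eigvalsh(np.linalg.inv(f.curvature)).max())
        for f in spec.funnels
    ])
    margin = 5.0 * spreads.max()
    lo5 = centers.min(axis=0) - margin
    hi5 = centers.max(axis=0) + margin
    rs = np.array([f.r_ref for f in spec.funnels])
    lo = np.concatenate([[max(rs.min() - 2.0, 1e-3)], lo5])
    hi = np.concatenate([[rs.max() + 2.0], hi5])
    return lo, hi


def default_funnel_spec(
    n_funnels: int = 1,
    rho_rug: float = 0.5,
    p_out: float = 0.1,
    separation: float = 3.0,
    seed: int = 0,
) -> FunnelSpec:
    """A realistic desk-scale landscape specification.

    Permissive eigenvalues ~2 (cluster spread ~0.7 rad at unit temperature)
    and restrictive >= 300 (spread < 0.06 rad): every permissive direction
    spreads at least ~10x wider than every restrictive one, so three
    principal components carry well over 75% of cluster variance, the
    wide-to-narrow pattern observed in real near-native docking clusters.
    Multiple funnels are placed ``separation`` apart in the permissive plane
    with slightly different depths and random orientations.
    """
    rng = np.random.default_rng(seed)
    funnels = []
    for j in range(n_funnels):
        lam = np.array([2.0, 2.2, 2.5, 300.0, 400.0])
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        A = Q @ np.diag(lam) @ Q.T
        A = 0.5 * (A + A.T)
        center = np.zeros(5)
        if n_funnels > 1:
            angle = 2.0 * np.pi * j / n_funnels
            direction = np.zeros(5)
            # offset in the permissive eigenplane so funnels stay resolvable
            direction[:2] = [np.cos(angle), np.sin(angle)]
            perm = Q[:, :2]  # small-eigenvalue directions of A
            center = perm @ direction[:2] * separation / 2.0
        funnels.append(
            Funnel(center=center, r_ref=25.0, depth=-10.0 + 0.5 * j, curvature=A)
        )
    return FunnelSpec(funnels=funnels, k_r=50.0, rho_rug=rho_rug,
                      p_out=p_out, seed=seed)


class ToyRigidEnergyModel(EnergyModel):
    """Soft-core Lennard-Jones + Coulomb energy over two rigid point sets.

    ``f(psi) = w_vdw * sum 4 eps [(sigma/r)^12 - (sigma/r)^6]
             + w_coul * k_C * sum q_i q_j / (eps_r * r_ij)``

    over receptor x placed-ligand atom pairs.  A soft-core floor replaces
    ``r_ij`` by ``max(r_ij, 0.6 sigma)`` in every pairwise term, so clash
    energies stay finite and bounded below, which underpins underestimation
    of minimized (non-clashing) structures.
    """

    def __init__(
        self,
        receptor: RigidBody,
        ligand: RigidBody,
        weights: EnergyWeights,
        lj_epsilon: float = 0.2,
        lj_sigma: float = 3.5,
        eps_r: float = 1.0,
    ):
        if receptor.n_atoms < 1 or ligand.n_atoms < 1:
            raise ValueError("both bodies must be non-empty")
        if weights.w_coul != 0.0 and (receptor.charges is None or ligand.charges is None):
            raise ValueError("Coulomb weight is non-zero but charges are missing")
        self.receptor = receptor
        self.ligand = ligand.centered()
        self.weights = weights
        self.lj_epsilon = float(lj_epsilon)
        self.lj_sigma = float(lj_sigma)
        self.eps_r = float(eps_r)

    def energy(self, psi: np.ndarray) -> float:
        placed = place_ligand(Conformation.from_psi(psi), self.ligand)
        D = cdist(self.receptor.coords, placed.coords)
        D = np.maximum(D, 0.6 * self.lj_sigma)  # soft-core floor on every term
        e = 0.0
        if self.weights.w_vdw != 0.0:
            sr6 = (self.lj_sigma / D) ** 6
            lj = 4.0 * self.lj_epsilon * (sr6**2 - sr6)
            e += self.weights.w_vdw * float(lj.sum())
        if self.weights.w_coul != 0.0:
            qq = np.outer(self.receptor.charges, self.ligand.charges)
            e += self.weights.w_coul * COULOMB_KCAL * float((qq / (self.eps_r * D)).sum())
        return e


def toy_rigid_energy(
    receptor: RigidBody,
    ligand: RigidBody,
    weights: EnergyWeights,
    lj_epsilon: float = 0.2,
    lj_sigma: float = 3.5,
    eps_r: float = 1.0,
) -> ToyRigidEnergyModel:
    """Construct the toy pairwise physical energy model (see class docs)."""
    return ToyRigidEnergyModel(receptor, ligand, weights, lj_epsilon, lj_sigma, eps_r)
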