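"""Rigid-body conformation parameterization and coordinate utilities.

A receptor--ligand placement is encoded as a 6-vector ``psi = (r, a, b, y1,
y2, y3)``: ``r`` is the receptor-to-ligand center distance in Angstrom,
``(a, b)`` are exponential coordinates of the direction of the translation
vector on the unit sphere, and ``y = (y1, y2, y3)`` is an axis-angle
(rotation-vector) parameterization of the ligand orientation.  The
refinement machinery works on the 5D reduction ``x = (a, b, y1, y2, y3)``
obtained by dropping ``r``, which varies little inside a well-packed
low-energy cluster.

Conventions (shared by every module in the package):

* ``direction_from_exp_coords(a, b)`` is the sphere exponential map anchored
  at the pole ``(0, 0, 1)``: rotate the pole by angle ``||(a, b)||`` about
  the axis ``(-b, a, 0) / ||(a, b)||``; ``(0, 0)`` maps to the pole itself.
* ``y`` is a global axis-angle vector (axis ``y/||y||``, angle ``||y||``),
  kept in the open ball ``||y|| < pi``; equivalent representatives outside
  the ball are re-wrapped so PCA on ``y`` is meaningful.
* RMSD between two placements of the same ligand is computed without
  superposition -- it is a distance between placements, not a structural
  alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Conformation",
    "RigidBody",
    "reduce",
    "attach_r",
    "wrap_rotation_vector",
    "direction_from_exp_coords",
    "rotation_from_tangent",
    "place_ligand",
    "rmsd",
    "read_pdb_rigid_body",
]

PSI_FIELDS = ("r", "a", "b", "y1", "y2", "y3")


@dataclass(frozen=True)
class Conformation:
    """A 6D rigid-body placement ``psi = (r, a, b, y1, y2, y3)``.

    ``r`` must be positive and every coordinate finite.  ``energy`` is
    optional and carries the value of whatever energy model produced or
    scored this conformation.
    """

    r: float
    a: float
    b: float
    y1: float
    y2: float
    y3: float
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        vec = (self.r, self.a, self.b, self.y1, self.y2, self.y3)
        if not all(np.isfinite(v) for v in vec):
            raise ValueError(f"conformation coordinates must be finite, got {vec}")
        if self.r <= 0:
            raise ValueError(f"center-to-center distance r must be positive, got {self.r}")
        if self.energy is not None and not np.isfinite(self.energy):
            raise ValueError(f"energy must be finite, got {self.energy}")

    @property
    def psi(self) -> np.ndarray:
        """The full 6-vector ``(r, a, b, y1, y2, y3)``."""
        return np.array([self.r, self.a, self.b, self.y1, self.y2, self.y3])

    @property
    def x(self) -> np.ndarray:
        """The reduced 5-vector ``(a, b, y1, y2, y3)`` (``r`` dropped)."""
        return np.array([self.a, self.b, self.y1, self.y2, self.y3])

    @property
    def y(self) -> np.ndarray:
        return np.array([self.y1, self.y2, self.y3])

    def with_energy(self, energy: float) -> "Conformation":
        return replace(self, energy=float(energy))

    @staticmethod
    def from_psi(psi: Sequence[float], energy: Optional[float] = None) -> "Conformation":
        psi = np.asarray(psi, dtype=float)
        if psi.shape != (6,):
            raise ValueError(f"psi must have 6 entries, got shape {psi.shape}")
        return Conformation(*psi, energy=energy)


@dataclass
class RigidBody:
    """A point-set rigid body: coordinates (Angstrom), optional charges.

    Coordinates of a ligand handed to :func:`place_ligand` are interpreted
    relative to the body centroid.  ``charges`` are in elementary-charge
    units; ``interface_mask`` optionally flags the atoms used for interface
    RMSD.
    """

    coords: np.ndarray
    charges: Optional[np.ndarray] = None
    interface_mask: Optional[np.ndarray] = None
    lj_epsilon: Optional[np.ndarray] = field(default=None, repr=False)
    lj_sigma: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or self.coords.shape[0] < 1:
            raise ValueError(f"coords must be an (n, 3) array with n >= 1, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (self.coords.shape[0],):
                raise ValueError("charges must match the number of atoms")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def centered(self) -> "RigidBody":
        """Copy with coordinates re-expressed relative to the centroid."""
        return RigidBody(
            self.coords - self.centroid,
            charges=None if self.charges is None else self.charges.copy(),
            interface_mask=None if self.interface_mask is None else self.interface_mask.copy(),
            lj_epsilon=self.lj_epsilon,
            lj_sigma=self.lj_sigma,
        )


def reduce(psi: Conformation) -> np.ndarray:
    """Drop ``r`` from a conformation, returning ``x = (a, b, y1, y2, y3)``."""
    if not isinstance(psi, Conformation):
        psi = Conformation.from_psi(psi)
    return psi.x


def attach_r(x: Sequence[float], r: float, energy: Optional[float] = None) -> Conformation:
    """Re-attach a center-to-center distance to reduced coordinates."""
    x = np.asarray(x, dtype=float)
    if x.shape != (5,):
        raise ValueError(f"reduced coordinates must have 5 entries, got shape {x.shape}")
    return Conformation(float(r), *x, energy=energy)


def wrap_rotation_vector(y: np.ndarray) -> np.ndarray:
    """Map an axis-angle vector to its representative with ``||y|| < pi``.

    ``y`` and ``y * (1 - 2*pi/||y||)`` encode the same rotation; the
    representative in the open ball of radius pi is unique except exactly on
    the boundary, where the one with non-negative leading component is kept.
    """
    y = np.asarray(y, dtype=float)
    theta = np.linalg.norm(y)
    if theta < np.pi or theta == 0.0:
        return y.copy()
    # reduce the angle modulo 2*pi into (-pi, pi]
    angle = np.remainder(theta, 2.0 * np.pi)
    if angle > np.pi:
        angle -= 2.0 * np.pi
    return y * (angle / theta)


def direction_from_exp_coords(a: float, b: float) -> np.ndarray:
    """Unit direction on S^2 from exponential coordinates ``(a, b)``.

    Exponential map anchored at the pole ``p = (0, 0, 1)``: rotate ``p`` by
    angle ``t = ||(a, b)||`` about the in-plane axis ``(-b, a, 0)/t``.  In
    closed form this is ``(a*sin(t)/t, b*sin(t)/t, cos(t))``, which to first
    order near the anchor is ``(a, b, 1)`` normalized.
    """
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError(f"exponential coordinates must be finite, got ({a}, {b})")
    t = float(np.hypot(a, b))
    if t < 1e-14:
        return np.array([0.0, 0.0, 1.0])
    s = np.sin(t) / t
    return np.array([a * s, b * s, np.cos(t)])


def rotation_from_tangent(y: Sequence[float]) -> np.ndarray:
    """Rotation matrix for the axis-angle (rotation-vector) ``y``.

    Rodrigues' formula with axis ``y/||y||`` and angle ``||y||``; ``y = 0``
    gives the identity.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (3,):
        raise ValueError(f"rotation vector must have 3 entries, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("rotation vector must be finite")
    theta = np.linalg.norm(y)
    if theta < 1e-14:
        return np.eye(3)
    k = y / theta
    K = np.array([[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def place_ligand(psi: Conformation, ligand: RigidBody) -> RigidBody:
    """Realize ``psi`` as atomic coordinates of the ligand.

    The ligand (coordinates relative to its centroid) is rotated by
    ``rotation_from_tangent(y)`` about its centroid, then translated so its
    centroid sits at ``r * direction_from_exp_coords(a, b)``, with the
    receptor centroid at the origin.
    """
    if not isinstance(psi, Conformation):
        psi = Conformation.from_psi(psi)  # validates r > 0 and finiteness
    R = rotation_from_tangent(psi.y)
    t = psi.r * direction_from_exp_coords(psi.a, psi.b)
    return RigidBody(
        ligand.coords @ R.T + t,
        charges=None if ligand.charges is None else ligand.charges.copy(),
        interface_mask=None if ligand.interface_mask is None else ligand.interface_mask.copy(),
        lj_epsilon=ligand.lj_epsilon,
        lj_sigma=ligand.lj_sigma,
    )


def rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square deviation between corresponding atoms, no superposition.

    ``sqrt(mean_i ||A_i - B_i||^2)`` -- a metric between placements of the
    same body, used as the cluster distance in post-processing.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape != B.shape or A.shape[0] < 1:
        raise ValueError(f"coordinate sets must have identical shape, got {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def read_pdb_rigid_body(path: str, chains: Optional[Sequence[str]] = None) -> RigidBody:
    """Read ATOM/HETATM records from a PDB file into a :class:`RigidBody`.

    Only the first altloc of each atom is kept; ``chains`` optionally
    restricts the selection.  Charges default to zero (toy-physics callers
    may overwrite them).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("body", path)
    model = next(structure.get_models())
    coords = []
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        for residue in chain:
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]
                coords.append(atom.get_coord())
    if not coords:
        raise ValueError(f"no atoms selected from {path!r} (chains={chains})")
    return RigidBody(np.asarray(coords, dtype=float))
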