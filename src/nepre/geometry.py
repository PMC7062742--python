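"""Per-residue local frames, spherical mapping, and rigid superposition.

Each residue defines a right-handed orthonormal frame anchored on its own
geometry: the origin is the residue's geometric center *o*, the +x axis points
from *o* to the backbone N atom, +y is the component of *o* -> CA orthogonal
to x (so CA always has a positive y coordinate), and z = x cross y.  Neighbor
positions expressed in this frame are rotation- and translation-invariant,
which is what makes the orientation statistics transferable between
structures.

Conventions: the polar angle theta in [0, pi] is measured from +z; the
azimuth phi in [0, 2*pi) is measured from +x toward +y; points on the polar
axis take phi = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateFrameError, IncompleteBackboneError
from .structure_io import Residue

#: Collinearity / coincidence tolerance for frame construction (A).
FRAME_DEGENERACY_TOL = 1e-6


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal frame (origin + three unit axes)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the axes as rows; maps lab vectors to frame coords."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, point: np.ndarray) -> np.ndarray:
        return self.rotation @ (np.asarray(point, dtype=float) - self.origin)

    def to_lab(self, local: np.ndarray) -> np.ndarray:
        return self.origin + self.rotation.T @ np.asarray(local, dtype=float)


@dataclass(frozen=True)
class SphericalPoint:
    """(r, theta, phi): radius in A, polar angle from +z, azimuth from +x."""

    r: float
    theta: float
    phi: float


def build_local_frame(residue: Residue) -> LocalFrame:
    """Construct the residue's local frame from its center, N, and CA atoms.

    Raises
    ------
    IncompleteBackboneError
        If the residue lacks an N or CA atom.
    DegenerateFrameError
        If N coincides with the center or N-o and CA-o are collinear
        (beyond ``FRAME_DEGENERACY_TOL``).
    """
    n_atom = residue.atom("N")
    ca_atom = residue.atom("CA")
    if n_atom is None or ca_atom is None:
        missing = "N" if n_atom is None else "CA"
        raise IncompleteBackboneError(
            f"residue {residue.label}: missing {missing} atom, cannot build frame"
        )
    origin = residue.center
    x_raw = n_atom.position - origin
    x_norm = np.linalg.norm(x_raw)
    if x_norm < FRAME_DEGENERACY_TOL:
        raise DegenerateFrameError(f"residue {residue.label}: N coincides with center")
    x_axis = x_raw / x_norm

    v = ca_atom.position - origin
    y_raw = v - (v @ x_axis) * x_axis
    y_norm = np.linalg.norm(y_raw)
    if y_norm < FRAME_DEGENERACY_TOL:
        raise DegenerateFrameError(
            f"residue {residue.label}: CA-o collinear with N-o, frame undefined"
        )
    y_axis = y_raw / y_norm
    z_axis = np.cross(x_axis, y_axis)
    return LocalFrame(origin=origin, x_axis=x_axis, y_axis=y_axis, z_axis=z_axis)


def cartesian_to_spherical(vec: np.ndarray) -> SphericalPoint:
    """Convert a Cartesian 3-vector to (r, theta, phi) with the package conventions."""
    x, y, z = (float(c) for c in vec)
    r = float(np.sqrt(x * x + y * y + z * z))
    if r == 0.0:
        return SphericalPoint(0.0, 0.0, 0.0)
    theta = float(np.arccos(np.clip(z / r, -1.0, 1.0)))
    if x == 0.0 and y == 0.0:
        phi = 0.0  # polar-axis convention
    else:
        phi = float(np.arctan2(y, x)) % (2.0 * np.pi)
    return SphericalPoint(r, theta, phi)


def to_local_spherical(frame: LocalFrame, point: np.ndarray) -> SphericalPoint:
    """Express a lab-frame point in the residue frame's spherical coordinates."""
    return cartesian_to_spherical(frame.to_local(point))


def spherical_to_cartesian(frame: LocalFrame, sph: SphericalPoint) -> np.ndarray:
    """Inverse of :func:`to_local_spherical`: reconstruct the lab-frame point."""
    st, ct = np.sin(sph.theta), np.cos(sph.theta)
    local = sph.r * np.array([st * np.cos(sph.phi), st * np.sin(sph.phi), ct])
    return frame.to_lab(local)


def local_spherical_arrays(frame: LocalFrame, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (r, theta, phi) of many lab points in one frame.

    Returns three arrays of shape (n,).  Matches :func:`to_local_spherical`
    pointwise, including the phi = 0 polar-axis convention.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    local = (pts - frame.origin) @ frame.rotation.T
    r = np.linalg.norm(local, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(r > 0, local[:, 2] / np.where(r > 0, r, 1.0), 1.0)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    phi = np.arctan2(local[:, 1], local[:, 0]) % (2.0 * np.pi)
    on_axis = (local[:, 0] == 0.0) & (local[:, 1] == 0.0)
    phi[on_axis] = 0.0
    theta[r == 0.0] = 0.0
    return r, theta, phi


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Least-squares RMSD after optimal rigid superposition (no reflection).

    The two coordinate lists are paired by index (typically CA atoms of the
    residues common to two structures).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or a.shape != b.shape:
        raise ValueError(f"coordinate arrays must both be (n, 3); got {a.shape} and {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired points for superposition, got {n}")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    # Kabsch: proper rotation (no reflection) minimizing sum |a - R b|^2
    u, _, vt = np.linalg.svd(a_c.T @ b_c)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    resid = a_c - b_c @ rot.T
    return float(np.sqrt((resid * resid).sum() / n))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix drawn from ``rng``."""
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix()
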